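code,vocabulary
I48,ICD10
G573400,READ2
G573500,READ2
3272.00,READ2
"3,272.00",READ2
G573000,READ2
G573300,READ2
G573.00,READ2
G573z00,READ2
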