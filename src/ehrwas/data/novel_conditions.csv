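condition
folic acid deficiency
pancytopenia
idiopathic thrombocytopenic purpura
seborrheic dermatitis
lymphoedema
angioedema
laryngopharyngeal reflux
rib fracture
haemorrhagic gastritis
inflammatory polyneuropathies
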