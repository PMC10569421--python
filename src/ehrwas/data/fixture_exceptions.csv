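period,setting,rank,label,code,printed_group,scheme_group,note
post,secondary,66,"Disease of pericardium, unspecified",I31.9,cardiac,vascular,printed under two different groups in the pre and post hospital lists; the scheme follows the pre-index placement
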