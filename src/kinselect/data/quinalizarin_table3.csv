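kinase,activity_percent,group_key,is_reference_target
CK2α (Human),42,,true
CK2α′ (Human),38,,true
CK2α (Zea mays),33,,true
CK2α2β2 (Human),10,,true
CK2α2′β2 (Human),14,,true
nCK2 (Rat liver),6,,true
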