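gene_id	group	has_paralog
bac0000	background	false
bac0001	background	true
mat0000	maternal	false
mat0001	maternal	false
pat0000	paternal	true
pat0001	paternal	true
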