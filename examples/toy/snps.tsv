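gene_id	coding_length_bp	snp_count
bac0000	90	0
bac0001	90	0
mat0000	90	0
mat0001	90	0
pat0000	90	1
pat0001	90	0
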