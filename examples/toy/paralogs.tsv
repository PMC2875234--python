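gene_id	paralog_id	rank	paralog_chromosome	protein_identity	n_paralogs
bac0001	bac0001_p1	1	20	63.08	2
pat0000	pat0000_p1	1	12	62.88	1
pat0001	pat0001_p1	1	X	56.77	1
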