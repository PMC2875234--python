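gene_id	species_a	species_b	protein_identity	cdna_identity	gap_count	ka	ks
bac0000	human	mouse	93.3333	88.8889	0	0.029488	0.53808
bac0000	human	rat	93.3333	87.7778	0	0.029488	0.643516
bac0000	mouse	rat	100.0	98.8889	0	-0.0	0.051745
bac0001	human	mouse	90.0	85.5556	0	0.044348	0.799764
bac0001	human	rat	90.0	86.6667	0	0.044348	0.668999
bac0001	mouse	rat	100.0	98.8889	0	-0.0	0.050867
mat0000	human	mouse	90.0	84.4444	0	0.046768	0.716634
mat0000	human	rat	86.6667	82.2222	0	0.062864	0.845389
mat0000	mouse	rat	96.6667	94.4444	0	0.015268	0.189986
mat0001	human	mouse	86.6667	85.5556	0	0.061102	0.598245
mat0001	human	rat	86.6667	85.5556	0	0.061102	0.598245
mat0001	mouse	rat	100.0	96.6667	0	-0.0	0.153072
pat0000	human	mouse	90.0	87.7778	0	0.05226	0.496049
pat0000	human	rat	90.0	87.7778	0	0.05226	0.496049
pat0000	mouse	rat	100.0	100.0	0	-0.0	-0.0
pat0001	human	mouse	90.0	90.0	0	0.043915	0.391642
pat0001	human	rat	90.0	88.8889	0	0.043915	0.482663
pat0001	mouse	rat	100.0	97.7778	0	-0.0	0.111315
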