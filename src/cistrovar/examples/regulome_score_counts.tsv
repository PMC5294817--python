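category	all_gwas_ld	under_peaks	trait_enriched
1a	21	1	0
1b	272	15	1
1c	6	0	0
1d	148	3	0
1e	7	0	0
1f	3182	43	5
2a	369	34	2
2b	3182	109	7
2c	137	8	0
universe	191482	572	42
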