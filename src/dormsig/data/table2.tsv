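sample_id	gene	dna_variant	dna_vaf	rna_variant	rna_vaf	cell_line_dna_variant
BBIRE-T 2691	BRAF	D594N	37	D594N	61	D594N
BBIRE-T 2393	BRAF	L597S	61	L597S	65	NA
BBIRE-T 1957	BRAF	V600E	83	V600E	31	WT
BBIRE-T 2217	BRAF	V600E	NA	V600E	72	V600E
BBIRE-T 1978	BRAF	V600E	20	V600E	68	V600E
BBIRE-T 2546	BRAF	V600E	34	V600E	38	V600E
BBIRE-T 1848	BRAF	V600E	28	V600E	30	WT
BBIRE-T 1918	BRAF	V600E	62	V600E	63	WT
BBIRE-T 2482	BRAF	V600E	60	V600E	75	WT
BBIRE-T 1841	BRAF	V600E	53	V600E	43	WT
BBIRE-T 2615	BRAF	V600E	32	WT	NA	V600E
BBIRE-T 2648	BRAF	V600E	47	V600E	70	V600E
BBIRE-T 1995	BRAF	V600K	72	V600K	87	V600K
BBIRE-T 2450	BRAF	V600K	34	V600K	55	NA
BBIRE-T 2108	BRAF	V600E	37	V600E	50	V600E
BBIRE-T 2177	BRAF	V600E	25	V600E	46	WT
BBIRE-T 2263	BRAF	V600K	NA	V600K	67	WT
BBIRE-T 1773	NRAS	G13D	16	G13D	80	WT
BBIRE-T 2061	NRAS	Q61K	42	Q61K	59	Q61K
BBIRE-T 2074	NRAS	Q61K	29	WT	NA	WT
BBIRE-T 2523	NRAS	Q61K	27	G13D	44	WT
BBIRE-T 2569	NRAS	Q61L	43	G13D	42	NA
BBIRE-T 2371	NRAS	Q61L	NA	Q61L	54	Q61L
BBIRE-T 1652	NRAS	Q61R	27	Q61R	33	Q61R
BBIRE-T 2542	BRAF	V600E	NA	WT	NA	NA
BBIRE-T 2658	NA	WT	NA	NA	NA	WT
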