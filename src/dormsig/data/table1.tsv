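sample_id	age	gender	driver_mutation	surgery_location	diagnosis	stage	t_stage
BBIRE-T 1652	75	F	NRAS p.Q61R	In-transit Metastasis	Melanoma	IIIB	4b
BBIRE-T 1773	74	F	NRAS p.G13D	In-transit Metastasis	Melanoma	IIB	4b
BBIRE-T 1841	55	F	BRAF p.V600E	In-transit Metastasis	Melanoma	IIIC	3b
BBIRE-T 1848	36	F	BRAF p.V600E	In-transit Metastasis	Melanoma	IIIC	3b
BBIRE-T 1918	48	F	BRAF p.V600E	In-transit Metastasis	Melanoma	IA	1a
BBIRE-T 1957	72	F	BRAF p.V600E	In-transit Metastasis	Melanoma	IV	4b(m)
BBIRE-T 1978	39	M	BRAF p.V600E	In-transit Metastasis	Melanoma	IB	2a
BBIRE-T 1995	54	F	BRAF p.V600K	In-transit Metastasis	Melanoma	IIIC	4b
BBIRE-T 2061	60	M	NRAS p.Q61K	In-transit Metastasis	Melanoma	IB	2a
BBIRE-T 2074	61	M	NRAS p.Q61K	In-transit Metastasis	Melanoma	IIC	4b
BBIRE-T 2108	66	F	BRAF p.V600E	In-transit Metastasis	Melanoma	IIIC	3b
BBIRE-T 2177	55	M	BRAF p.V600E	In-transit Metastasis	Melanoma	IIIA	2a
BBIRE-T 2217	59	M	BRAF p.V600E	In-transit Metastasis	Melanoma	IV	x
BBIRE-T 2263	55	M	BRAF p.V600K	In-transit Metastasis	Melanoma	IIB	3b
BBIRE-T 2371	76	F	NRAS p.Q61L	In-transit Metastasis	Melanoma	IIIC	3b
BBIRE-T 2393	55	M	BRAF p.L597S	In-transit Metastasis	Melanoma	IIIB	2b
BBIRE-T 2450	63	M	BRAF p.V600K	In-transit Metastasis	Melanoma	IIID	4b
BBIRE-T 2482	55	M	BRAF p.V600E	In-transit Metastasis	Melanoma	IV	x
BBIRE-T 2523	78	M	NRAS p.Q61K	In-transit Metastasis	Melanoma	IIIB	3a
BBIRE-T 2542	59	M	BRAF p.V600E	In-transit Metastasis	Melanoma	IV	4b
BBIRE-T 2546	56	M	BRAF p.V600E	In-transit Metastasis	Melanoma	IV	3b
BBIRE-T 2569	85	F	NRAS p.Q61L	In-transit Metastasis	Melanoma	IIIC	4a
BBIRE-T 2615	73	F	BRAV p.V600E	In-transit Metastasis	Melanoma	IIID	4b
BBIRE-T 2648	73	M	BRAF p.V600E	In-transit Metastasis	Melanoma	IIC	T4b
BBIRE-T 2658	83	F	WT	In-transit Metastasis	Melanoma	IV	t4a
BBIRE-T 2691	86	F	BRAF p.D594N	In-transit Metastasis	Melanoma	NA	t3b
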