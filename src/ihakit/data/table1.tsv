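mag_id	status	size_mbp	n50_mbp	n_contigs	gc	completeness	contamination	cds	rrna	trna
H1_BAC1		3.379	3.379	1	0.460	98.5	0.3	3138	3	40
H1_PLA1		3.610	3.610	1	0.700	98.9	0.0	3039	3	49
H1_PLA2	Circular	3.877	3.877	1	0.633	96.6	0.0	3140	3	51
H1_AMX1	Circular	3.495	3.495	1	0.425	100.0	1.6	3099	3	47
H1_AOB3		2.842	2.842	1	0.512	100.0	0.3	2674	3	43
H1_ARM1	Circular	2.897	2.897	1	0.609	94.9	0.9	2665	3	48
H1_PLA3	Circular	3.887	3.887	1	0.673	96.6	0.0	3032	3	53
H1_PLA4	Circular	3.841	3.841	1	0.672	97.7	0.0	3229	3	54
H1_AOB1	Circular	3.279	3.279	1	0.499	99.8	0.0	3122	3	38
H1_CFX2		4.791	4.742	4	0.531	93.6	3.6	4575	3	50
H1_AOB2	Circular	3.217	3.217	1	0.495	99.9	0.0	3074	3	39
H1_BAC2		2.842	2.842	1	0.495	97.0	1.1	2326	6	44
H1_PLA5		5.011	3.408	4	0.610	97.7	1.1	4106	3	52
H1_PLA6		5.026	3.822	2	0.650	97.7	1.7	4074	3	51
H2_CFX3		4.684	1.286	5	0.566	100.0	2.7	3904	6	49
H2_MYX1		9.475	3.220	5	0.698	93.9	2.6	8465	3	79
H2_BAC3	Circular	4.213	4.213	1	0.441	98.9	0.0	3318	3	43
H2_PRO1		3.105	3.105	1	0.686	91.0	1.5	2810	3	51
H3_ACI1		2.971	1.982	2	0.538	96.6	2.6	2688	3	47
H3_CFX4		3.148	1.455	4	0.667	93.1	1.0	3207	3	48
H3_PLA7		3.869	0.987	5	0.653	94.3	3.4	3180	3	67
H5_SPI1		4.129	2.456	4	0.531	96.5	0.0	4087	3	40
H5_BAC4		3.186	2.101	3	0.388	99.5	1.7	2670	3	42
H5_UNCL1		4.583	2.293	3	0.545	96.6	2.7	3627	3	49
H5_CFX6		2.882	1.591	2	0.525	92.7	0.9	2714	3	48
H5_SPI2		3.423	2.007	4	0.346	100.0	0.0	3317	6	37
H5_BAC6		3.824	2.408	4	0.348	99.4	0.0	3310	3	44
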