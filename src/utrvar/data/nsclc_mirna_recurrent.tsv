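gene	mRNA	UTR	snv	mirna	dG_WT	dG_SNV	dbsnp
CALM1	NM_006888	3	C2472G	hsa-miR-29a-3p	N/A	-16.70
CKLF	NM_016326	5	U72G	hsa-miR-29a-3p	N/A	-20.70
IGFBP5	NM_000599	3	G3898U	hsa-miR-29a-3p	N/A	-13.83	rs13403592
CALM1	NM_006888	3	C2472G	hsa-miR-29b-3p	N/A	-18.12
CKLF	NM_016326	5	U72G	hsa-miR-29b-3p	N/A	-18.76
IGFBP5	NM_000599	3	G3898U	hsa-miR-29b-3p	N/A	-11.93	rs13403592
CALM1	NM_006888	3	C2472G	hsa-miR-29c-3p	N/A	-15.13
CKLF	NM_016326	5	U72G	hsa-miR-29c-3p	N/A	-18.83
IGFBP5	NM_000599	3	G3898U	hsa-miR-29c-3p	N/A	-12.71	rs13403592
SUZ12	NM_015355	3	C2473G	hsa-miR-30a-3p	-12.66	-8.97
SUZ12	NM_015355	3	G2475U	hsa-miR-30a-3p	-12.66	-6.32
SUZ12	NM_015355	3	U2474A	hsa-miR-30a-3p	-12.66	-6.86
SUZ12	NM_015355	3	C2473G	hsa-miR-30e-3p	-12.53	-8.02
SUZ12	NM_015355	3	G2475U	hsa-miR-30e-3p	-12.53	-6.19
SUZ12	NM_015355	3	U2474A	hsa-miR-30e-3p	-12.53	-6.73
BCL2L13	NM_001270731	3	U1850G	hsa-miR-361-3p	N/A	-17.85	rs725768
SDC4	NM_002999	3	U1874G	hsa-miR-361-3p	-15.88	-20.18
SOX4	NM_003107	3	G4753A	hsa-miR-361-3p	-20.76	-14.48	rs11556729
BCL2L13	NM_001270731	3	U2269A	hsa-miR-519b-3p	N/A	-11.07	rs74932682
JAK1	NM_002227	3	U5007A	hsa-miR-519b-3p	-16.69	-12.31
OSMR	NM_003999	3	C4534U	hsa-miR-519b-3p	N/A	-13.92
FAM46C	NM_017709	3	A1459G	hsa-miR-614	-17.89	-22.28	rs2066411
KLF10	NM_005655	3	C2615A	hsa-miR-614	-22.30	-17.54	rs6935
RHEB	NM_005614	3	A1229G	hsa-miR-614	N/A	-15.19
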