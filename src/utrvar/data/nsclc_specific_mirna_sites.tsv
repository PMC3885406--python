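gene	mRNA	UTR	snv	mirna	dG_WT	dG_SNV	dbsnp
DHCR24	NM_014762	3	A4192C	hsa-miR-7-5p	N/A	-11.85
EIF4EBP2	NM_004096	3	C5092G	hsa-miR-15b-5p	-16.10	-10.65
EIF4EBP2	NM_004096	3	C5092G	hsa-miR-16-5p	-18.20	-13.97
EIF4EBP2	NM_004096	3	C5092G	hsa-miR-195-5p	-17.63	-12.23
KIF3B	NM_004798	3	G5433A	hsa-miR-184	-21.40	-14.40	rs41289846
MED16	NM_005481	5	A129U	hsa-miR-184	N/A	-20.65
SUZ12	NM_015355	3	C2473G	hsa-miR-30a-3p	-12.66	-8.97
SUZ12	NM_015355	3	C2473G	hsa-miR-30d-3p	-11.68	-8.65
SUZ12	NM_015355	3	C2473G	hsa-miR-30e-3p	-12.53	-8.02
SUZ12	NM_015355	3	G2475U	hsa-miR-30a-3p	-12.66	-6.32
SUZ12	NM_015355	3	G2475U	hsa-miR-30d-3p	-11.68	-5.57
SUZ12	NM_015355	3	G2475U	hsa-miR-30e-3p	-12.53	-6.19
SUZ12	NM_015355	3	U2474A	hsa-miR-30a-3p	-12.66	-6.86
SUZ12	NM_015355	3	U2474A	hsa-miR-30e-3p	-12.53	-6.73
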