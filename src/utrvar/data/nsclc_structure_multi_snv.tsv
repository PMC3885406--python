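gene	mRNA	UTR	snv	p_value	measure	overlap_pct	source	dbsnp
SH3PXD2A	NM_014631	3	C8560U	0.0223	d	100	rnaz
SH3PXD2A	NM_014631	3	U8562A	0.0451	d	100	rnaz
MAPK1	NM_002745	3	G1633A	0.0815	d	100	cmfinder	rs41282607
MAPK1	NM_002745	3	U2360G	0.0148	d	100	cmfinder	rs13058
ACOX1	NM_004035	3	U4708G	0.0650	d	100	cmfinder
ACOX1	NM_004035	3	A6386U	0.0750	d	59	cmfinder
ADAMTS1	NM_006988	3	U4320G	0.0166	d	94	cmfinder
ADAMTS1	NM_006988	3	U3449C	0.0626	d	86	rnaz
CDC42	NM_001039802	5	C159A	0.0665	d	100	rnaz
CDC42	NM_001039802	5	G152A	0.0901	d	100	rnaz
ID2	NM_002166	5	C143G	0.0464	d	87	cmfinder
ID2	NM_002166	5	C129G	0.069	d	87	cmfinder
NFKBIE	NM_004556	3	G1659C	0.0144	d	84	cmfinder
NFKBIE	NM_004556	3	U1644G	0.0333	d	98	cmfinder
RASSF1	NM_170714	3	A1907U	0.0629	d	64	cmfinder
RASSF1	NM_170714	3	G1904A	0.0659	d	64	cmfinder
RXRB	NM_021976	3	U2066G	0.0268	d	59	cmfinder	rs2744537
RXRB	NM_021976	3	U2053A	0.0452	d	73	cmfinder	rs5030979
PCBP4	NM_001174100	3	U1862G	0.0401	d	93	cmfinder
PCBP4	NM_001174100	3	C1790G	0.0413	d	59	cmfinder
MTA2	NM_004739	5	A227G	0.0462	d	73	cmfinder
BECN1	NM_003766	3	U1970C	0.012	d	100	cmfinder
CTSB	NM_147782	3	A2561G	0.0569	d	100	rnaz
HTT	NM_002111	3	C9948G	0.0987	d	100	cmfinder	rs362305
HTT	NM_002111	3	U9947C	0.0225	r	100	cmfinder
BECN1	NM_003766	3	G2053A	0.0329	r	98	cmfinder	rs11552193
LMNB2	NM_032737	3	A3713G	0.0554	r	59	cmfinder
LMNB2	NM_032737	3	U3662C	0.0638	r	57	cmfinder
CTSB	NM_147782	3	A2581G	0.0925	r	50	rnaz
MTA2	NM_004739	5	C267G	0.1035	r	53	cmfinder
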