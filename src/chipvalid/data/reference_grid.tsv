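gene	variant	variant_class	concentration	expected_vaf	observed_vaf	depth	uao
ABL1	T315I	SNP	1.0	0.0500	0.0481	1433	47
ABL1	T315I	SNP	0.25	0.0125	0.0093	1395	12
ABL1	T315I	SNP	0.0625	0.0031	0.0046	1463	7
ABL1	T315I	SNP	0.03125	0.0016	0.0029	1723	5
ABL1	T315I	SNP	0.015625	0.0008
ASXL1	c.1934dup	INS	1.0	0.4000	0.3099	6287	445
ASXL1	c.1934dup	INS	0.25	0.1000	0.0815	6995	216
ASXL1	c.1934dup	INS	0.0625	0.0250	0.0411	7215	148
ASXL1	c.1934dup	INS	0.03125	0.0125	0.0337	7611	132
ASXL1	c.1934dup	INS	0.015625	0.0063
ASXL1	W796C	SNP	1.0	0.0500	0.0487	2993	86
ASXL1	W796C	SNP	0.25	0.0125	0.0110	2813	25
ASXL1	W796C	SNP	0.0625	0.0031	0.0034	2274	7
ASXL1	W796C	SNP	0.03125	0.0016
ASXL1	W796C	SNP	0.015625	0.0008
CBL	S403F	SNP	1.0	0.0500	0.0540	1571	63
CBL	S403F	SNP	0.25	0.0125	0.0099	1781	17
CBL	S403F	SNP	0.0625	0.0031	0.0047	2395	11
CBL	S403F	SNP	0.03125	0.0016	0.0029	2115	6
CBL	S403F	SNP	0.015625	0.0008
FLT3	c.2503G>T	SNP	1.0	0.0500	0.0144	4429	32
FLT3	c.2503G>T	SNP	0.25	0.0125	0.0034	5443	15
FLT3	c.2503G>T	SNP	0.0625	0.0031	0.0012	5057	5
FLT3	c.2503G>T	SNP	0.03125	0.0016
FLT3	c.2503G>T	SNP	0.015625	0.0008
GATA2	G200Vfs*18	DEL	1.0	0.3500	0.3372	1962	216
GATA2	G200Vfs*18	DEL	0.25	0.0875	0.0687	1694	72
GATA2	G200Vfs*18	DEL	0.0625	0.0219	0.0166	1429	19
GATA2	G200Vfs*18	DEL	0.03125	0.0109	0.0073	1686	11
GATA2	G200Vfs*18	DEL	0.015625	0.0055	0.0055	1566	8
IDH1	R132C	SNP	1.0	0.0500	0.0407	3765	91
IDH1	R132C	SNP	0.25	0.0125	0.0085	4855	33
IDH1	R132C	SNP	0.0625	0.0031	0.0033	5240	16
IDH1	R132C	SNP	0.03125	0.0016	0.0017	6219	10
IDH1	R132C	SNP	0.015625	0.0008	0.0014	4241	6
JAK2	F537-K539>L	DEL	1.0	0.0500	0.0442	1558	43
JAK2	F537-K539>L	DEL	0.25	0.0125	0.0101	2148	17
JAK2	F537-K539>L	DEL	0.0625	0.0031	0.0037	2381	7
JAK2	F537-K539>L	DEL	0.03125	0.0016
JAK2	F537-K539>L	DEL	0.015625	0.0008
JAK2	V617F	SNP	1.0	0.0500	0.0502	2444	83
JAK2	V617F	SNP	0.25	0.0125	0.0112	2969	28
JAK2	V617F	SNP	0.0625	0.0031	0.0029	3170	9
JAK2	V617F	SNP	0.03125	0.0016
JAK2	V617F	SNP	0.015625	0.0008
KRAS	G13D	SNP	1.0	0.4000	0.4036	1612	213
KRAS	G13D	SNP	0.25	0.1000	0.0819	2074	90
KRAS	G13D	SNP	0.0625	0.0250	0.0158	1727	16
KRAS	G13D	SNP	0.03125	0.0125	0.0073	2449	15
KRAS	G13D	SNP	0.015625	0.0063	0.0032	2352	8
NPM1	W288Cfs*12	INS	1.0	0.0500	0.0262	1342	30
NPM1	W288Cfs*12	INS	0.25	0.0125	0.0084	1402	11
NPM1	W288Cfs*12	INS	0.0625	0.0031
NPM1	W288Cfs*12	INS	0.03125	0.0016
NPM1	W288Cfs*12	INS	0.015625	0.0008
NRAS	Q61L	SNP	1.0	0.1000	0.1029	1688	66
NRAS	Q61L	SNP	0.25	0.0250	0.0215	2092	31
NRAS	Q61L	SNP	0.0625	0.0063	0.0058	1413	6
NRAS	Q61L	SNP	0.03125	0.0031	0.0027	2454	6
NRAS	Q61L	SNP	0.015625	0.0016
SF3B1	G740E	SNP	1.0	0.0500	0.0477	4572	123
SF3B1	G740E	SNP	0.25	0.0125	0.0086	5951	43
SF3B1	G740E	SNP	0.0625	0.0031	0.0024	3255	6
SF3B1	G740E	SNP	0.03125	0.0016	0.0014	3930	10
SF3B1	G740E	SNP	0.015625	0.0008	0.0011	5430	6
TET2	R1261H	SNP	1.0	0.0500	0.0476	1112	36
TET2	R1261H	SNP	0.25	0.0125	0.0100	1325	12
TET2	R1261H	SNP	0.0625	0.0031	0.0045	1308	6
TET2	R1261H	SNP	0.03125	0.0016	0.0038	1583	5
TET2	R1261H	SNP	0.015625	0.0008
TP53	S241F	SNP	1.0	0.0500	0.0510	3242	93
TP53	S241F	SNP	0.25	0.0125	0.0095	3595	32
TP53	S241F	SNP	0.0625	0.0031	0.0022	1738	7
TP53	S241F	SNP	0.03125	0.0016	0.0018	4326	7
TP53	S241F	SNP	0.015625	0.0008	0.0015	4008	6
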