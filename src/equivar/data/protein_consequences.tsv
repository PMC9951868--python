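gene	chrom	pos	hgvsp	annotation	mw_difference	hydropathy_difference
FAAH	2	12167952	A96V	non-synonymous coding	28.06	0.46
FAAH	2	12174477	A13V	non-synonymous coding	28.06	0.46
FAAH	2	12174492	A8D	non-synonymous coding	44.01	-1.52
PER3	2	43209639	L837S	non-synonymous coding	-26.08	-1.24
PER3	2	43231315	V465A	non-synonymous coding	-28.06	-0.46
PER3	2	43240108	K241N	non-synonymous coding	-14.07	0.72
CDH13	3	31079056	Y20H	non-synonymous coding	-26.04	-0.66
CDH13	3	31230472	V95I	non-synonymous coding	14.02	0.3
CDH13	3	31382147	R173W;R134W	non-synonymous coding	30.03	3.34
CDH13	3	31845727	S696F;S657F	non-synonymous coding	60.1	1.37
NPY	4	55899514	T139S	non-synonymous coding	-14.03	-0.13
LEP	4	83529565	T70M	splice site region non-synonymous coding	30.09	0.69
HSD11B1	5	25786262	Y88S	non-synonymous coding	-76.1	-0.44
ANKK1	7	22319266	I10V	non-synonymous coding	-14.02	-0.3
ANKK1	7	22319267	I10N	non-synonymous coding	0.95	-2.16
ANKK1	7	22319365	E43Q	non-synonymous coding	-0.98	1.22
ANKK1	7	22319396	L53P	non-synonymous coding	-16.04	-0.94
ANKK1	7	22319430	E64D	non-synonymous coding	-14.03	-0.16
ANKK1	7	22319446	T70A	non-synonymous coding	-30.03	0.67
ANKK1	7	22319470	E78K	non-synonymous coding	-0.94	-0.76
ANKK1	7	22326586	I287V	non-synonymous coding	-14.02	-0.3
ANKK1	7	22327351	R337H	non-synonymous coding	-19.05	2.13
ANKK1	7	22329824	R411W	non-synonymous coding	30.03	3.34
ANKK1	7	22330242	R550Q	non-synonymous coding	-28.05	3.01
ANKK1	7	22331004	A804D	non-synonymous coding	44.01	-1.52
ANKK1	7	22331042	E817K	non-synonymous coding	-0.94	-0.76
DRD2	7	22348064	K101I	non-synonymous coding	-15.02	2.88
BDNF	7	96310373	H14Q	non-synonymous coding	-9	0.88
COMT	8	432351	T231A	non-synonymous coding	-30.03	0.67
COMT	8	434481	M159T	non-synonymous coding	-30.09	-0.69
P2RX7	8	24214858	S589G	non-synonymous coding	-30.02	0.66
APOE	10	15713778	Q17R	non-synonymous coding	28.05	-3.01
APOE	10	15714427	M100V	non-synonymous coding	-32.06	0.44
APOE	10	15714824	V232G	non-synonymous coding	-42.08	-0.6
CNR1	10	41805559	V263I	non-synonymous coding	14.02	0.3
SLC6A4	11	44188160	V539A	non-synonymous coding	-28.06	-0.46
SLC6A4	11	44188161	V539I	non-synonymous coding	14.02	0.3
SLC6A4	11	44192165	I408V	non-synonymous coding	-14.02	-0.3
SLC6A4	11	44200439	D36E	non-synonymous coding	14.03	0.16
GABRA6	14	17329705	I423M	non-synonymous coding	18.04	-0.74
GABRA6	14	17329709	R422Q	non-synonymous coding	-28.05	3.01
GABRA6	14	17329851	S375T	non-synonymous coding	14.03	0.13
GABRA6	14	17329886	H363R	splice site region non-synonymous coding	19.05	-2.13
GABRA6	14	17338413	V352A	non-synonymous coding	-28.06	-0.46
GABRA6	14	17343960	E30K	non-synonymous coding	-0.94	-0.76
HTR2A	17	23797786	T39A	non-synonymous coding	-30.03	0.67
DGKH	17	27918092	S631Y	non-synonymous coding	76.1	0.44
DGKH	17	28048492	V12A	non-synonymous coding	-28.06	-0.46
MAOA	X	36799409	C24R	non-synonymous coding	53.04	-2.82
MAOA	X	36799613	G92S	non-synonymous coding	30.02	-0.66
MAOA	X	36800118	A142G;A260G	non-synonymous coding	-14.02	-0.14
MAOA	X	36800211	L173P;L291P	non-synonymous coding	-16.04	-0.94
MAOA	X	36800238	S182SSFPFLGSSQVSVLGSAPPSVPSSPWSSVQG;S300SSFPFLGSSQVSVLGSAPPSVPSSPWSSVQG	codon insertion	NA	NA
MAOA	X	36800403	W237L;W355L	non-synonymous coding	-73.06	0.25
MAOA	X	36801932	N307T	non-synonymous coding	-13	0.73
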