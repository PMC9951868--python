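gene	chrom	pos	ref_allele	alt_allele	ref_freq	alt_freq
FAAH	2	12167952	G	A	0.995	0.005
FAAH	2	12174477	G	A	0.936	0.064
FAAH	2	12174492	G	T	0.955	0.045
PER3	2	43209639	A	G	0.683	0.317
PER3	2	43231315	A	G	0.678	0.322
PER3	2	43240108	C	A	0.822	0.178
CDH13	3	31079056	T	C	0.911	0.089
CDH13	3	31230472	G	A	0.955	0.045
CDH13	3	31382147	C	T	0.757	0.243
CDH13	3	31845727	C	T	0.995	0.005
NPY	4	55899514	C	G	0.861	0.139
LEP	4	83529565	C	T	0.891	0.109
HSD11B1	5	25786262	T	G	0.767	0.233
ANKK1	7	22319266	A	G	0.782	0.218
ANKK1	7	22319267	T	A	0.787	0.213
ANKK1	7	22319365	G	C	0.772	0.228
ANKK1	7	22319396	T	C	0.995	0.005
ANKK1	7	22319430	G	T	0.995	0.005
ANKK1	7	22319446	A	G	0.782	0.218
ANKK1	7	22319470	G	A	0.787	0.213
ANKK1	7	22326586	A	G	0.698	0.302
ANKK1	7	22327351	G	A	0.698	0.302
ANKK1	7	22329824	C	T	0.975	0.025
ANKK1	7	22330242	G	A	0.995	0.005
ANKK1	7	22331004	C	A	0.960	0.040
ANKK1	7	22331042	G	A	0.941	0.059
DRD2	7	22348064	T	A	0.995	0.005
BDNF	7	96310373	A	T	0.812	0.188
COMT	8	432351	T	C	0.842	0.158
COMT	8	434481	A	G	0.886	0.114
P2RX7	8	24214858	A	G	0.644	0.356
APOE	10	15713778	A	G	0.995	0.005
APOE	10	15714427	A	G	0.832	0.168
APOE	10	15714824	T	G	0.995	0.005
CNR1	10	41805559	C	T	0.946	0.054
SLC6A4	11	44188160	A	G	0.332	0.668
SLC6A4	11	44188161	C	T	0.332	0.668
SLC6A4	11	44192165	T	C	0.985	0.015
SLC6A4	11	44200439	A	C	0.970	0.030
GABRA6	14	17329705	A	C	0.950	0.050
GABRA6	14	17329709	C	T	0.842	0.158
GABRA6	14	17329851	A	T	0.777	0.223
GABRA6	14	17329886	T	C	0.985	0.015
GABRA6	14	17338413	A	G	0.673	0.327
GABRA6	14	17343960	C	T	0.926	0.074
HTR2A	17	23797786	A	G	0.990	0.010
DGKH	17	27918092	G	T	0.832	0.168
DGKH	17	28048492	A	G	0.985	0.015
MAOA	X	36799409	T	C	NA	NA
MAOA	X	36799613	G	A	NA	NA
MAOA	X	36800118	C	G	NA	NA
MAOA	X	36800211	T	C	NA	NA
MAOA	X	36800238	C	CATCTTTCCCGTTCTTGGGCTCCTCCCAAGTGTCGGTACTAGGGTCCGCCCCGCCATCAGTGCCAACTCCCCCTGGAGTTCGGTACAAGG	NA	NA
MAOA	X	36800403	G	T	NA	NA
MAOA	X	36801932	A	C	NA	NA
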