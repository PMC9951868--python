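code	three_letter	mass	hydropathy_consensus	hydropathy_paper
A	Ala	89.09	0.62	0.62
R	Arg	174.20	-2.53	-2.53
N	Asn	132.12	-0.78	-0.78
D	Asp	133.10	-0.90	-0.90
C	Cys	121.16	0.29	0.29
Q	Gln	146.15	-0.85	0.48
E	Glu	147.13	-0.74	-0.74
G	Gly	75.07	0.48	0.48
H	His	155.15	-0.40	-0.40
I	Ile	131.17	1.38	1.38
L	Leu	131.17	1.06	1.06
K	Lys	146.19	-1.50	-1.50
M	Met	149.21	0.64	0.64
F	Phe	165.19	1.19	1.19
P	Pro	115.13	0.12	0.12
S	Ser	105.09	-0.18	-0.18
T	Thr	119.12	-0.05	-0.05
W	Trp	204.23	0.81	0.81
Y	Tyr	181.19	0.26	0.26
V	Val	117.15	1.08	1.08
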