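feature_id	fold_change	adjusted_p	regulation
YOD1	0.27	0.0321	Lower
EPHX2	2.21	0.0336	Higher
PDGFC	0.36	0.0373	Lower
CD8B2	2.15	0.0146	Higher
TRIM58	0.38	0.0340	Lower
RHPN1	2.10	0.0157	Higher
TENT5C	0.40	0.0343	Lower
KLK1	2.04	0.0349	Higher
XK	0.40	0.0456	Lower
PLEKHB1	1.95	0.0326	Higher
TMOD1	0.40	0.0256	Lower
TCF7	1.95	0.0419	Higher
JAZF1	0.40	0.0455	Lower
CD248	1.93	0.0135	Higher
RNF11	0.40	0.0346	Lower
FHIT	1.91	0.0420	Higher
SNCA	0.40	0.0370	Lower
CD8B	1.90	0.0457	Higher
FOXO3	0.41	0.0275	Lower
CCR10	1.81	0.0451	Higher
GCLC	0.41	0.0403	Lower
C12orf57	1.81	0.0411	Higher
KAT2B	0.42	0.0414	Lower
NPM3	1.78	0.0180	Higher
FURIN	0.43	0.0348	Lower
PCSK4	1.76	0.0114	Higher
TPM1	0.44	0.0330	Lower
C1QTNF6	1.75	0.0437	Higher
RHOBTB1	0.45	0.0460	Lower
IQCN	1.74	0.0365	Higher
SLC7A5	0.45	0.0450	Lower
ASIC1	1.74	0.0141	Higher
PIP5K1B	0.45	0.0368	Lower
FXYD2	1.73	0.0401	Higher
CTNNAL1	0.46	0.0345	Lower
TMIGD2	1.72	0.0370	Higher
RAP2A	0.46	0.0439	Lower
NRCAM	1.72	0.0317	Higher
CALD1	0.47	0.0451	Lower
HIST1H1D	1.71	0.0375	Higher
FNBP1L	0.47	0.0321	Lower
NOSIP	1.69	0.0326	Higher
ARHGAP6	0.48	0.0371	Lower
TLE2	1.66	0.0356	Higher
CREG1	0.49	0.0362	Lower
AMIGO1	1.66	0.0459	Higher
TBCEL	0.50	0.0445	Lower
SYNE4	1.66	0.0349	Higher
GCNT1	0.50	0.0320	Lower
PTPRCAP	1.64	0.0340	Higher
GSPT1	0.50	0.0401	Lower
SELENOM	1.64	0.0458	Higher
RIOK3	0.50	0.0445	Lower
SOX8	1.64	0.0457	Higher
PDCD10	0.50	0.0374	Lower
KLHL34	1.63	0.0209	Higher
ABCB10	0.50	0.0458	Lower
NPY4R	1.62	0.0404	Higher
TTC7B	0.51	0.0326	Lower
GSDMB	1.61	0.0444	Higher
DNAJC6	0.51	0.0340	Lower
LIG1	1.61	0.0110	Higher
ADIPOR1	0.51	0.0346	Lower
FAM174B	1.60	0.0350	Higher
RGS1	0.52	0.0449	Lower
SLC27A5	1.60	0.0430	Higher
NRP1	0.52	0.0358	Lower
RPL36	1.60	0.0255	Higher
TMC5	0.52	0.0167	Lower
HPDL	1.58	0.0460	Higher
BNIP3L	0.52	0.0322	Lower
SCML4	1.58	0.0255	Higher
RIPOR3	0.52	0.0118	Lower
CD7	1.57	0.0353	Higher
STOM	0.53	0.0341	Lower
COL6A1	1.57	0.0373	Higher
DNM3	0.53	0.0349	Lower
VILL	1.56	0.0456	Higher
NIPSNAP3A	0.53	0.0432	Lower
MYL6B	1.56	0.0454	Higher
F13A1	0.53	0.0422	Lower
MTFP1	1.56	0.0330	Higher
FAM104A	0.53	0.0313	Lower
C19orf48	1.55	0.0369	Higher
TFDP1	0.53	0.0372	Lower
GPC2	1.54	0.0311	Higher
XYLT1	0.53	0.0451	Lower
SFI1	1.54	0.0328	Higher
CLIC2	0.53	0.0117	Lower
MRNIP	1.54	0.0124	Higher
RHCE	0.53	0.0420	Lower
CD27	1.54	0.0406	Higher
MKRN1	0.53	0.0373	Lower
MST1R	1.53	0.0404	Higher
TUBB1	0.54	0.0463	Lower
ZFP90	1.53	0.0441	Higher
PTPRF	0.54	0.0192	Lower
TEDC1	1.53	0.0341	Higher
SRXN1	0.54	0.0158	Lower
ATP5IF1	1.53	0.0314	Higher
DAB2	0.54	0.0461	Lower
SPEG	1.52	0.0440	Higher
SFRP2	0.54	0.0453	Lower
ZNF692	1.52	0.0120	Higher
SLC25A37	0.54	0.0433	Lower
STMN3	1.52	0.0452	Higher
PIP4K2A	0.55	0.0179	Lower
ZNF444	1.52	0.0115	Higher
GP6	0.56	0.0413	Lower
TMEM160	1.51	0.0358	Higher
GUCY1B1	0.56	0.0473	Lower
TESPA1	1.51	0.0314	Higher
HRH4	0.56	0.0422	Lower
ADAMTS13	1.51	0.0156	Higher
EPB41	0.57	0.0372	Lower
PBX4	1.51	0.0458	Higher
VEGFC	0.57	0.0438	Lower
ATAD3B	1.50	0.0431	Higher
HEXIM1	0.57	0.0385	Lower
HNMT	0.57	0.0444	Lower
DACH1	0.58	0.0357	Lower
GAPT	0.58	0.0363	Lower
RPIA	0.58	0.0412	Lower
MPP1	0.58	0.0333	Lower
COPS2	0.58	0.0458	Lower
CHMP4B	0.59	0.0323	Lower
P2RY12	0.59	0.0460	Lower
FAM117A	0.59	0.0458	Lower
BMP6	0.59	0.0370	Lower
DCAF6	0.59	0.0242	Lower
MPL	0.60	0.0446	Lower
CA8	0.60	0.0410	Lower
GOLM1	0.60	0.0473	Lower
ACPP	0.60	0.0317	Lower
STON1	0.60	0.0458	Lower
RNF10	0.60	0.0373	Lower
BHLHE40	0.61	0.0370	Lower
SNX3	0.61	0.0411	Lower
SPTA1	0.61	0.0348	Lower
WNK1	0.61	0.0421	Lower
CLEC5A	0.61	0.0403	Lower
RAB27B	0.61	0.0442	Lower
KLRB1	0.61	0.0459	Lower
ODC1	0.62	0.0345	Lower
OPTN	0.62	0.0453	Lower
ATP6V0C	0.62	0.0358	Lower
TAL1	0.62	0.0460	Lower
DHX29	0.62	0.0460	Lower
ZNF469	0.62	0.0345	Lower
UBE2E3	0.63	0.0459	Lower
VCL	0.63	0.0359	Lower
HK1	0.63	0.0366	Lower
KIF1B	0.63	0.0482	Lower
LRP12	0.63	0.0440	Lower
PCDH9	0.64	0.0464	Lower
TFPI	0.64	0.0459	Lower
LTBP1	0.64	0.0342	Lower
VLDLR	0.64	0.0451	Lower
BMP2K	0.65	0.0375	Lower
RNF14	0.65	0.0418	Lower
SELENOK	0.65	0.0334	Lower
C2orf76	0.66	0.0310	Lower
SLC6A4	0.66	0.0456	Lower
CTNNA1	0.66	0.0461	Lower
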