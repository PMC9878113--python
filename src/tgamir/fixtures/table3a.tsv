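feature_id	fold_change	adjusted_p	regulation
TMOD1	0.47	0.0321	Lower
LRRN3	2.47	0.0394	Higher
PRSS33	0.52	0.0270	Lower
TRABD2A	1.84	0.0448	Higher
SFRP2	0.55	0.0493	Lower
CD8B2	1.84	0.0206	Higher
RGS1	0.55	0.0485	Lower
PLEKHB1	1.71	0.0210	Higher
SRXN1	0.55	0.0181	Lower
IQCN	1.71	0.0340	Higher
RHCE	0.56	0.0444	Lower
CD248	1.70	0.0306	Higher
TFDP1	0.59	0.0298	Lower
IL7R	1.69	0.0449	Higher
DNAJC6	0.59	0.0476	Lower
TMIGD2	1.66	0.0274	Higher
HRH4	0.59	0.0433	Lower
C1QTNF6	1.62	0.0480	Higher
PTPRF	0.60	0.0286	Lower
NRCAM	1.61	0.0357	Higher
NRP1	0.60	0.0466	Lower
ASIC1	1.56	0.0449	Higher
RIPOR3	0.60	0.0204	Lower
NPM3	1.56	0.0382	Higher
DACH1	0.61	0.0444	Lower
GSDMB	1.56	0.0425	Higher
STOM	0.61	0.0347	Lower
NOSIP	1.54	0.0362	Higher
TMC5	0.62	0.0350	Lower
PTPRCAP	1.54	0.0237	Higher
MPP1	0.64	0.0440	Lower
PBX4	1.52	0.0203	Higher
OXER1	0.64	0.0300	Lower
OFD1	1.50	0.0209	Higher
CLEC5A	0.65	0.0218	Lower
SCML4	1.50	0.0278	Higher
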