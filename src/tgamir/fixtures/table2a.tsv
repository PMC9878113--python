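feature_id	fold_change	adjusted_p	regulation
miR-494-3p	0.47	0.0240	Lower
miR-150-5p	0.50	0.0003	Lower
miR-125a-5p	0.50	0.0099	Lower
miR-342-3p	0.51	0.0001	Lower
miR-99b-5p	0.52	0.0049	Lower
miR-145-5p	0.59	0.0120	Lower
miR-199a-5p	0.61	0.0384	Lower
miR-1246	0.61	0.0120	Lower
miR-93-3p	0.62	0.0003	Lower
miR-193b-3p	0.62	0.0025	Lower
miR-361-5p	0.62	0.0003	Lower
miR-15b-3p	0.63	0.0153	Lower
miR-6794-3p	0.63	0.0135	Lower
miR-532-3p	0.63	0.0025	Lower
miR-23a-3p	0.63	0.0161	Lower
miR-6125	0.63	0.0192	Lower
miR-4732-5p	0.63	0.0207	Lower
miR-942-5p	0.63	0.0172	Lower
miR-128-3p	0.63	0.0006	Lower
miR-23b-3p	0.65	0.0129	Lower
miR-629-3p	0.66	0.0117	Lower
miR-1275	0.66	0.0492	Lower
miR-139-5p	0.66	0.0192	Lower
miR-454-5p	0.67	0.0157	Lower
miR-6819-3p	1.59	0.0011	Higher
miR-103a-3p	1.59	0.0492	Higher
miR-29b-3p	1.67	0.0240	Higher
miR-590-5p	1.70	0.0208	Higher
miR-140-5p	1.71	0.0194	Higher
miR-106b-5p	1.74	0.0038	Higher
miR-29c-3p	1.74	0.0135	Higher
miR-301a-3p	1.77	0.0135	Higher
miR-148a-3p	1.81	0.0210	Higher
miR-17-3p	2.29	0.0044	Higher
miR-18b-5p	2.30	0.0012	Higher
miR-18a-5p	2.58	0.0051	Higher
miR-101-3p	2.64	0.0135	Higher
miR-144-5p	2.81	0.0455	Higher
miR-144-3p	3.08	0.0429	Higher
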