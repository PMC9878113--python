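feature_id	fold_change	adjusted_p	regulation
miR-4665-3p	0.58	0.0223	Lower
miR-4505	0.59	0.0110	Lower
miR-4299	0.63	0.0123	Lower
miR-1306-5p	1.50	0.0240	Higher
miR-21-3p	1.53	0.0346	Higher
miR-6803-3p	1.54	0.0224	Higher
miR-22-5p	1.55	0.0110	Higher
miR-378a-3p	1.56	0.0224	Higher
miR-574-3p	1.57	0.0240	Higher
miR-296-5p	1.57	0.0257	Higher
miR-1255b-5p	1.59	0.0240	Higher
miR-505-3p	1.59	0.0284	Higher
miR-501-3p	1.60	0.0427	Higher
miR-5690	1.60	0.0308	Higher
miR-3200-3p	1.61	0.0110	Higher
miR-193b-3p	1.62	0.0110	Higher
miR-93-3p	1.62	0.0206	Higher
miR-212-3p	1.63	0.0350	Higher
miR-4449	1.65	0.0110	Higher
miR-664a-5p	1.66	0.0240	Higher
miR-211-3p	1.66	0.0341	Higher
miR-378g	1.66	0.0259	Higher
miR-6073	1.68	0.0384	Higher
miR-629-3p	1.70	0.0110	Higher
miR-15b-3p	1.71	0.0308	Higher
miR-3200-5p	1.71	0.0492	Higher
miR-500b-5p	1.72	0.0164	Higher
miR-6794-3p	1.73	0.0110	Higher
miR-664a-3p	1.74	0.0350	Higher
miR-181b-5p	1.75	0.0240	Higher
miR-1260b	1.77	0.0405	Higher
miR-339-3p	1.79	0.0110	Higher
miR-3907	1.79	0.0110	Higher
miR-99a-5p	1.80	0.0110	Higher
miR-4732-5p	1.80	0.0308	Higher
miR-454-5p	1.84	0.0017	Higher
miR-99b-5p	1.85	0.0259	Higher
miR-340-5p	1.85	0.0259	Higher
miR-500a-5p	1.86	0.0308	Higher
miR-1246	1.87	0.0110	Higher
miR-339-5p	1.88	0.0240	Higher
miR-378a-5p	1.88	0.0484	Higher
miR-186-5p	1.89	0.0341	Higher
miR-378d	1.93	0.0223	Higher
miR-942-5p	1.99	0.0110	Higher
miR-6085	2.12	0.0127	Higher
miR-30a-5p	2.20	0.0492	Higher
miR-6826-5p	2.30	0.0223	Higher
miR-145-5p	2.31	0.0110	Higher
miR-125b-5p	2.44	0.0240	Higher
miR-3135b	2.79	0.0061	Higher
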