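feature_id	fold_change	adjusted_p	regulation
miR-99b-5p	0.39	0.0012	Lower
miR-145-5p	0.39	0.0013	Lower
miR-125a-5p	0.41	0.0012	Lower
miR-125b-5p	0.41	0.0079	Lower
miR-150-5p	0.43	0.0010	Lower
miR-342-3p	0.43	0.0004	Lower
miR-494-3p	0.44	0.0156	Lower
miR-3135b	0.44	0.0065	Lower
miR-484	0.45	0.0156	Lower
miR-1246	0.45	0.0007	Lower
miR-4428	0.45	0.0275	Lower
miR-942-5p	0.45	0.0023	Lower
miR-8485	0.47	0.0160	Lower
miR-4732-5p	0.48	0.0079	Lower
miR-6794-3p	0.48	0.0006	Lower
miR-15b-3p	0.48	0.0013	Lower
miR-409-3p	0.48	0.0329	Lower
miR-326	0.49	0.0145	Lower
miR-378a-5p	0.49	0.0156	Lower
miR-93-3p	0.49	0.0004	Lower
miR-339-5p	0.49	0.0079	Lower
miR-193b-3p	0.49	0.0004	Lower
miR-454-5p	0.50	0.0003	Lower
miR-199a-5p	0.50	0.0087	Lower
miR-629-3p	0.51	0.0013	Lower
miR-186-5p	0.52	0.0423	Lower
miR-574-3p	0.54	0.0004	Lower
miR-532-3p	0.54	0.0019	Lower
miR-5189-3p	0.54	0.0393	Lower
miR-6789-5p	0.54	0.0431	Lower
miR-361-5p	0.54	0.0002	Lower
miR-3200-5p	0.54	0.0114	Lower
miR-99a-5p	0.55	0.0013	Lower
miR-361-3p	0.57	0.0164	Lower
miR-191-5p	0.57	0.0106	Lower
miR-139-5p	0.57	0.0079	Lower
miR-505-3p	0.57	0.0065	Lower
miR-6125	0.57	0.0102	Lower
miR-151a-3p	0.57	0.0156	Lower
miR-664a-3p	0.57	0.0256	Lower
miR-30c-5p	0.57	0.0329	Lower
miR-3200-3p	0.58	0.0017	Lower
miR-128-3p	0.58	0.0006	Lower
miR-30b-5p	0.58	0.0300	Lower
miR-5690	0.58	0.0046	Lower
miR-4672	0.58	0.0195	Lower
miR-423-3p	0.58	0.0156	Lower
miR-23a-3p	0.58	0.0093	Lower
miR-574-5p	0.59	0.0300	Lower
miR-4732-3p	0.59	0.0329	Lower
miR-2861	0.59	0.0232	Lower
miR-92a-3p	0.59	0.0065	Lower
miR-7-1-3p	0.60	0.0058	Lower
miR-1275	0.61	0.0304	Lower
miR-4449	0.61	0.0170	Lower
miR-501-3p	0.61	0.0279	Lower
miR-5001-5p	0.62	0.0221	Lower
miR-7704	0.62	0.0303	Lower
miR-10a-5p	0.63	0.0080	Lower
miR-4721	0.63	0.0410	Lower
miR-1271-5p	0.63	0.0140	Lower
miR-1268b	0.63	0.0489	Lower
miR-6803-3p	0.63	0.0080	Lower
miR-23b-3p	0.63	0.0184	Lower
miR-6513-3p	0.63	0.0017	Lower
miR-212-3p	0.64	0.0233	Lower
miR-654-3p	0.64	0.0156	Lower
miR-296-5p	0.64	0.0284	Lower
miR-3180-3p	0.64	0.0327	Lower
miR-222-3p	0.64	0.0376	Lower
miR-3605-3p	0.65	0.0050	Lower
miR-324-3p	0.65	0.0036	Lower
miR-130b-5p	0.65	0.0079	Lower
miR-1268a	0.66	0.0326	Lower
miR-423-5p	0.66	0.0384	Lower
miR-6511b-3p	0.66	0.0238	Lower
miR-29b-3p	1.58	0.0384	Higher
miR-4713-3p	1.64	0.0384	Higher
miR-4665-3p	1.64	0.0164	Higher
miR-4433a-5p	1.66	0.0046	Higher
miR-29c-3p	1.70	0.0122	Higher
miR-3198	1.70	0.0405	Higher
miR-5581-5p	1.72	0.0304	Higher
miR-6131	1.72	0.0393	Higher
miR-1305	1.74	0.0304	Higher
miR-6740-5p	1.75	0.0398	Higher
miR-33b-3p	1.77	0.0106	Higher
miR-6819-3p	1.86	0.0037	Higher
miR-6717-5p	1.88	0.0203	Higher
miR-106b-5p	1.90	0.0069	Higher
miR-301a-3p	1.97	0.0310	Higher
miR-19a-3p	2.03	0.0160	Higher
miR-17-5p	2.34	0.0491	Higher
miR-18b-5p	2.65	0.0079	Higher
miR-17-3p	2.67	0.0126	Higher
miR-96-5p	2.78	0.0471	Higher
miR-20a-5p	2.86	0.0310	Higher
miR-18a-5p	3.22	0.0144	Higher
miR-101-3p	3.59	0.0164	Higher
miR-144-5p	5.01	0.0097	Higher
miR-144-3p	6.40	0.0156	Higher
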