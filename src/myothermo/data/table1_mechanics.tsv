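phase	time_min	vmax_mean	vmax_sd	tension_mean	tension_sd	f1_mean	f1_sd	g1_mean	g1_sd	g2_mean	g2_sd
anoxia	0	3.8	0.7	51	19	314	83	199	69	753	148
anoxia	30	3.6	0.8	44	17	369	102	281	108	726	166
anoxia	60	3.2	0.8	37	14	364	96	321	114	639	160
anoxia	90	2.9	0.8	30	14	367	127	357	140	583	168
anoxia	120	2.5	0.8	28	12	359	103	388	118	491	151
anoxia	150	2.2	0.8	22	10	331	85	383	109	444	126
anoxia	180	2.0	0.8	20	8	306	108	358	143	398	141
recovery	30	2.9	0.7	32	12	283	96	201	100	581	149
recovery	60	3.2	0.7	38	13	276	73	174	60	639	139
recovery	90	3.4	0.9	38	15	290	100	157	99	673	174
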