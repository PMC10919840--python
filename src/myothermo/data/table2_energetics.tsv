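phase	time_min	myosin_content_mean	myosin_content_sd	v0_mean	v0_sd	max_efficiency_pct_mean	max_efficiency_pct_sd	cb_force_mean	cb_force_sd
anoxia	0	13.9	5.4	5.1	1.9	28	2	1.6	0.1
anoxia	30	14.1	5.2	6.5	2.5	26	3	1.5	0.1
anoxia	60	12.9	4.8	7.8	3.1	22	2	1.4	0.1
anoxia	90	11.4	4.6	8.2	3.5	21	2	1.3	0.1
anoxia	120	10.5	4.6	8.9	2.8	19	2	1.2	0.1
anoxia	150	9.5	3.6	8.6	3.1	18	2	1.2	0.1
anoxia	180	7.9	3.4	8.0	3.0	18	2	1.2	0.1
recovery	30	10.4	3.9	4.6	2.4	27	3	1.5	0.1
recovery	60	11.2	3.9	4.2	1.9	28	2	1.6	0.1
recovery	90	11.1	4.9	4.1	2.2	28	3	1.6	0.1
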