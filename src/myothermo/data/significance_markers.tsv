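table	contrast	vmax	tension	f1	g1	g2	myosin_content	v0	max_efficiency	cb_force
1	C_vs_180	***	***	NS	***	***	.	.	.	.
1	180_vs_r90	§§§	§	NS	§§§	§§§	.	.	.	.
1	C_vs_r90	NS	!!!	NS	NS	NS	.	.	.	.
2	C_vs_180	.	.	.	.	.	***	***	***	***
2	180_vs_r90	.	.	.	.	.	§	§§§	§§§	§§§
2	C_vs_r90	.	.	.	.	.	!	NS	NS	NS
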