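timepoint	RI	BH	BT	CA	unknown
12	0.083778	0.035507	0.023773	0.087737	0.128904
25	0.265497	0.187063	0.190103	0.206035	0.171997
37	0.188714	0.108122	0.156754	0.180169	0.142749
49	0.146688	0.129058	0.182511	0.217926	0.145821
61	0.307789	0.138084	0.234025	0.173425	0.193095
67	0.272897	0.152637	0.247013	0.18302	0.170893
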