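timepoint	RI	BH	BT	CA	unknown
12	0.08524	0.036112	0.022186	0.088633	0.130591
25	0.214333	0.010937	0.007273	0.046363	0.030389
37	0.214488	0.028629	0.053429	0.077235	0.029701
49	0.073805	0.01982	0.057038	0.117559	0.051704
61	0.169425	0.034899	0.128028	0.224111	0.053825
67	0.139789	0.056921	0.107093	0.103975	0.024723
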