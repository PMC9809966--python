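timepoint	SUCROSE	GLUCOSE	PYRUVIC	SUCCINIC	LACTIC	FORMIC	ACETIC	PROPIONIC	BUTYRIC	ISO-VALERIC
12	0.244388	0.858503	0.072397	0.083457	0.02851	0.021789	0.044231	0.463254	0.148036	0.440977
25	0.017016	0.145383	0.005845	0.024062	0.056295	0.012329	0.012509	0.011448	0.056756	0.10848
37	0.015275	0.075146	0.026605	0.036005	0.033019	0.043567	0.01939	0.013149	0.034249	0.016311
49	0.006412	0.081673	0.030288	0.028576	0.038954	0.038535	0.015391	0.006143	0.035086	0.00906
61	0.008326	0.15639	0.023726	0.037439	0.044986	0.08773	0.023782	0.011166	0.048077	0.01169
67	0.027965	0.128629	0.031992	0.051787	0.044778	0.081846	0.023155	0.015654	0.043894	0.014131
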