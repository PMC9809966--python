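timepoint	RI	BH	BT	CA	PC	Pseudomonas
12	0.113239276	0.397144213	0.172832451	0.60641672	1.242717343	2.236067977
25	0.33068139	0.22071944	0.210248005	0.287588766	1.003694528	1.415466593
37	0.102026264	0.146570623	0.120770959	0.172268032	2.236067977	2.236067977
49	0.186705056	0.140052997	0.138907605	0.222581161	2.236067977	1.530790053
61	0.324258986	0.176068622	0.187582764	0.176863057		
67	0.292911099	0.162137207	0.184128334	0.226700163		1.447941079
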