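timepoint	RI	BH	BT	CA	PC	Pseudomonas
12	0.15564025	0.342347337	0.084569975	0.444253232	1.253757964	2.236067977
25	0.245641378	0.12732518	0.072919997	0.229917778	1.00863528	1.42241808
37	0.142818618	0.045539634	0.032834755	0.226996463	2.236067977	2.236067977
49	0.141334216	0.026952911	0.040465197	0.126509944	2.236067977	1.506706746
61	0.184331535	0.016473304	0.01774408	0.175607974		
67	0.193706912	0.032947196	0.036114669	0.094963831		1.520979059
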