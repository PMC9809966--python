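# 16S rRNA gene copy numbers per community member.
# Placeholder values (1): fill in strain-exact copy numbers from rrnDB
# (https://rrndb.umms.med.umich.edu/) before real analyses.
species	copy_number
Roseburia intestinalis	1
Blautia hydrogenotrophica	1
Bacteroides thetaiotaomicron	1
Collinsella aerofaciens	1
Prevotella copri	1
Faecalibacterium prausnitzii	1
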