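isolate	total_sm	nrps_pool	pks_pool	hybrids	tc
B. meristosporus CBS 931.73	26/44 (61%)	22/30 (60%)	2/4 (50%)	0/0 (0%)	2/10 (2%)
B. meristosporus B9252	12/44 (27%)	9/30 (30%)	1/7 (14%)	0/1 (0%)	2/6 (1.4%)
B. heterosporus B8920	7/23 (30%)	7/18 (40%)	0/1 (0%)	0/0 (0%)	0/4 (0%)
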