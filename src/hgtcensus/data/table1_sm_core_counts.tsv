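isolate	total_sm	nrps_pool	pks_pool	hybrids	tc
B. meristosporus CBS 931.73	44	30	4	0	10
B. meristosporus B9252	44	30	7	1	6
B. heterosporus B8920	23	18	1	0	4
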