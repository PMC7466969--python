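isolate	gene_id	z	sm_class	donor_taxonomy
B. heterosporus B8920	N168_02885	-0.104	NRPS	b-proteobacteria
B. heterosporus B8920	N168_05934	-0.183	NRPS	b-proteobacteria
B. heterosporus B8920	N168_07140	0.260	NRPS	b-proteobacteria
B. heterosporus B8920	N168_06479	0.328	NRPS	b-proteobacteria
B. heterosporus B8920	N168_00176	0.013	NRPS	cyanobacteria
B. heterosporus B8920	N168_05966	0.672	NRPS	d-proteobacteria
B. heterosporus B8920	N168_08580	0.047	NRPS-Like	d-proteobacteria
B. meristosporus B9252	N161.mRNA.1431.1	-0.350	NRPS	cyanobacteria
B. meristosporus B9252	N161.mRNA.1485.1	-0.258	NRPS	d-proteobacteria
B. meristosporus B9252	N161.mRNA.4115.1	0.158	NRPS	enterobacteria
B. meristosporus B9252	N161.mRNA.4324.1	0.213	NRPS	CFB group bacteria
B. meristosporus B9252	N161.mRNA.8304.1	0.358	NRPS	b-proteobacteria
B. meristosporus B9252	N161.mRNA.11289.1	0.596	NRPS	cyanobacteria
B. meristosporus B9252	N161.mRNA.1486.1	0.662	NRPS-Like	firmicutes
B. meristosporus B9252	N161.mRNA.6846.1	0.760	NRPS-Like	firmicutes
B. meristosporus B9252	N161.mRNA.8699.1	-0.201	NRPS-Like	firmicutes
B. meristosporus B9252	N161.mRNA.6146.1	0.999	PKS	high GC Gram+
B. meristosporus B9252	N161.mRNA.1413.1	0.481	Terpene	CFB group bacteria
B. meristosporus B9252	N161.mRNA.13969.1	1.099	Terpene	CFB group bacteria
B. meristosporus CBS 931.73	366903	0.043	NRPS	a-proteobacteria
B. meristosporus CBS 931.73	368581	-0.232	NRPS	b-proteobacteria
B. meristosporus CBS 931.73	349800	0.208	NRPS	high GC Gram+
B. meristosporus CBS 931.73	351909	-0.120	NRPS	cyanobacteria
B. meristosporus CBS 931.73	372749	-0.088	NRPS	firmicutes
B. meristosporus CBS 931.73	372991	-0.260	NRPS	b-proteobacteria
B. meristosporus CBS 931.73	373247	0.533	NRPS	firmicutes
B. meristosporus CBS 931.73	373940	-0.142	NRPS	firmicutes
B. meristosporus CBS 931.73	375475	0.522	NRPS	enterobacteria
B. meristosporus CBS 931.73	338397	0.033	NRPS	d-proteobacteria
B. meristosporus CBS 931.73	375580	0.033	NRPS	cyanobacteria
B. meristosporus CBS 931.73	375613	-0.369	NRPS	firmicutes
B. meristosporus CBS 931.73	377413	-0.245	NRPS	g-proteobacteria
B. meristosporus CBS 931.73	387529	-0.157	NRPS	b-proteobacteria
B. meristosporus CBS 931.73	307892	0.404	NRPS	a-proteobacteria
B. meristosporus CBS 931.73	298977	-0.201	NRPS	b-proteobacteria
B. meristosporus CBS 931.73	343011	0.147	NRPS	firmicutes
B. meristosporus CBS 931.73	363930	-0.358	NRPS	firmicutes
B. meristosporus CBS 931.73	300898	-0.165	NRPS-Like	firmicutes
B. meristosporus CBS 931.73	322666	-0.174	NRPS-Like	CFB group bacteria
B. meristosporus CBS 931.73	146993	-0.200	NRPS-Like	cyanobacteria
B. meristosporus CBS 931.73	382467	-0.264	NRPS-Like	a-proteobacteria
B. meristosporus CBS 931.73	340613	-0.136	NRPS-Like	GNS bacteria
B. meristosporus CBS 931.73	237744	-0.001	PKS	bacteria
B. meristosporus CBS 931.73	292783	-0.429	PKS	high GC Gram+
B. meristosporus CBS 931.73	301341	-0.210	Terpene	CFB group bacteria
B. meristosporus CBS 931.73	304520	0.389	Terpene	cyanobacteria
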