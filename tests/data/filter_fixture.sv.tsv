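SAMPLE	CHROM1	POS1	CHROM2	POS2	TYPE
S1	chrT	2000000	chrT	2009999	deletion
S2	chrT	2000000	chrT	2010000	deletion
S3	chrT	2000000	chrU	2000000	interchromosomal
S4	chrT	4200000	chrU	2000000	interchromosomal
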