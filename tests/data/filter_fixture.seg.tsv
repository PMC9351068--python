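SAMPLE	CHROM	START	END	MEDIAN_LOGR	DIRECTION
S1	chrT	2000001	3999999	0.15	gain
S2	chrT	2000001	3999999	0.16	gain
S3	chrT	2000001	3999999	-0.15	loss
S4	chrT	2000001	3999999	-0.16	loss
S5	chrT	2000001	3999999	0.0	cn_loh
S6	chrT	2000001	2009999	0.4	gain
S7	chrT	2000001	2010000	0.4	gain
S8	chrT	1000000	3000000	0.4	gain
S9	chrT	1000002	3000000	0.4	gain
S10	chrT	6000001	9000002	0.4	gain
S11	chrT	6000001	8999999	0.4	gain
S12	chrT	4100001	6000000	0.4	gain
S13	chrT	1	10000000	-0.3	loss
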