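##fileformat=VCFv4.2
##contig=<ID=chrT,length=10000000>
##contig=<ID=chrU,length=10000000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=POPAF,Number=1,Type=String,Description="Population allele frequency">
##INFO=<ID=CLASS,Number=1,Type=String,Description="SNV or indel">
##INFO=<ID=REGION,Number=1,Type=String,Description="coding or noncoding">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Functional effect">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
chrT	100	.	A	T	.	.	DP=6;POPAF=0.0
chrT	200	.	A	T	.	.	DP=7;POPAF=0.0
chrT	300	.	C	G	.	.	DP=7;POPAF=0.002
chrT	400	.	C	G	.	.	DP=7;POPAF=0.001
chrT	500	.	G	A	.	.	DP=7
chrT	600	.	G	A	.	.	DP=6;POPAF=0.002
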