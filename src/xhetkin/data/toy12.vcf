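##fileformat=VCFv4.2
##source=xhetkin-docs-toy-fixture
##contig=<ID=chrX>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	TOY1
chrX	2781478	.	A	T	.	.	.	GT:AD:DP:GQ	0/1:15,15:30:99
chrX	2781479	.	C	G	.	.	.	GT:AD:DP:GQ	0/1:15,15:30:99
chrX	5000000	.	A	T	.	.	.	GT:AD:DP:GQ	0/1:30,10:40:99
chrX	5000100	.	G	C	.	.	.	GT:AD:DP:GQ	0/1:37,13:50:99
chrX	5000200	.	T	A	.	.	.	GT:AD:DP:GQ	0/1:10,10:20:99
chrX	5000300	.	C	T	.	.	.	GT:AD:DP:GQ	0/1:10,11:21:60
chrX	6000000	.	A	G	.	.	.	GT:AD:DP:GQ	0/0:30,0:30:99
chrX	6000100	.	C	T	.	.	.	GT	./.
chrX	7000000	.	G	A	.	.	.	GT:AD:DP:GQ	1/1:0,30:30:99
chrX	7000100	.	T	C	.	.	.	GT:AD:DP:GQ	1:0,25:25:75
chrX	153925834	.	A	C	.	.	.	GT:AD:DP:GQ	1/1:1,29:30:99
chrX	153925835	.	A	G	.	.	.	GT:AD:DP:GQ	0/1:15,15:30:99
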