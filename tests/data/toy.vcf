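##fileformat=VCFv4.2
##source=hand-written-fixture
##contig=<ID=ctg1,length=2000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	S1
ctg1	100	.	A	T	.	PASS	.	GT:AD:DP	0/0/1/1:3,4:7
ctg1	200	.	C	G	.	PASS	.	GT:AD:DP	0/0/0/1:9,1:10
ctg1	300	.	G	A	.	PASS	.	GT:AD:DP	0/0/0/1:95,5:100
ctg1	400	.	T	C	.	PASS	.	GT:AD:DP	0/0/1/1:20,20:40
ctg1	500	.	A	ATG	.	PASS	.	GT:AD:DP	0/0/0/1:7,1:8
ctg1	600	.	C	T	.	PASS	.	GT:AD:DP	0/0/0/0:8,0:8
ctg1	700	.	G	C	.	PASS	.	GT:AD:DP	0/0/1/1:20,10:30
ctg1	800	.	T	A	.	PASS	.	GT:AD:DP	0/0/0/1:44,4:50
ctg1	900	.	A	G,C	.	PASS	.	GT:AD:DP	0/0/1/2:30,6,4:40
ctg1	1000	.	C	A	.	PASS	.	GT:DP	0/0/0/1:12
ctg1	1100	.	G	T	.	PASS	.	GT:AD:DP	0/1/1/1:1,8:9
ctg1	1200	.	T	G	.	PASS	.	GT:AD:DP	1/1/1/1:0,7:7
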