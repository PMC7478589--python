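##fileformat=VCFv4.2
##contig=<ID=chr1,length=2000>
##INFO=<ID=LOC,Number=1,Type=String,Description="GBS locus id">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	i1	i2	i3	i4	i5	i6
chr1	100	s1	A	C	.	PASS	LOC=L1	GT:DP	0/0:20	0/0:20	0/1:20	0/0:20	1/1:20	0/0:20
chr1	200	s2	A	C	.	PASS	LOC=L2	GT:DP	0/0:20	0/1:20	./.:.	./.:.	./.:.	0/0:20
chr1	300	s3	A	C	.	PASS	LOC=L3	GT:DP	0/0:5	0/0:5	0/0:5	0/1:5	0/1:5	0/0:5
chr1	400	s4	A	C	.	PASS	LOC=L4	GT:DP	0/1:20	0/1:20	0/1:20	0/1:20	0/0:20	1/1:20
chr1	500	s5	A	C	.	PASS	LOC=L5	GT:DP	0/1:20	0/1:20	0/1:20	0/0:20	1/1:20	./.:.
chr1	600	s6	A	C	.	PASS	LOC=L6	GT:DP	0/0:7	0/0:7	0/0:7	0/0:7	0/1:7	0/0:7
chr1	700	s7	A	C	.	PASS	LOC=L7	GT:DP	1/1:20	1/1:20	1/1:20	1/1:20	1/1:20	1/1:20
chr1	800	s8	A	C	.	PASS	LOC=L8	GT:DP	0/0:20	0/1:20	0/0:20	0/0:20	0/0:20	./.:.
chr1	900	s9	A	C	.	PASS	LOC=L9	GT:DP	0/0:20	0/0:20	0/1:20	0/1:20	0/0:20	0/0:20
chr1	1000	s10	A	C	.	PASS	LOC=L9	GT:DP	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/1:20
chr1	1100	s11	A	C	.	PASS	LOC=L10	GT:DP	0/0:20	0/0:20	0/0:20	0/1:20	0/0:20	./.:.
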