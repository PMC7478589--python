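# Hand-read ALT allele-copy counts for toy.vcf ('.' = missing call)
site	i1	i2	i3	i4	i5	i6
s1	0	0	1	0	2	0
s2	0	1	.	.	.	0
s3	0	0	0	1	1	0
s4	1	1	1	1	0	2
s5	1	1	1	0	2	.
s6	0	0	0	0	1	0
s7	2	2	2	2	2	2
s8	0	1	0	0	0	.
s9	0	0	1	1	0	0
s10	1	0	0	0	0	1
s11	0	0	0	1	0	.
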