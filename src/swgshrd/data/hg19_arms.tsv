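chrom	arm	start	end
chr1	p	0	125000000
chr1	q	125000000	249250621
chr2	p	0	93300000
chr2	q	93300000	243199373
chr3	p	0	91000000
chr3	q	91000000	198022430
chr4	p	0	50400000
chr4	q	50400000	191154276
chr5	p	0	48400000
chr5	q	48400000	180915260
chr6	p	0	61000000
chr6	q	61000000	171115067
chr7	p	0	59900000
chr7	q	59900000	159138663
chr8	p	0	45600000
chr8	q	45600000	146364022
chr9	p	0	49000000
chr9	q	49000000	141213431
chr10	p	0	40200000
chr10	q	40200000	135534747
chr11	p	0	53700000
chr11	q	53700000	135006516
chr12	p	0	35800000
chr12	q	35800000	133851895
chr13	p	0	17900000
chr13	q	17900000	115169878
chr14	p	0	17600000
chr14	q	17600000	107349540
chr15	p	0	19000000
chr15	q	19000000	102531392
chr16	p	0	36600000
chr16	q	36600000	90354753
chr17	p	0	24000000
chr17	q	24000000	81195210
chr18	p	0	17200000
chr18	q	17200000	78077248
chr19	p	0	26500000
chr19	q	26500000	59128983
chr20	p	0	27500000
chr20	q	27500000	63025520
chr21	p	0	13200000
chr21	q	13200000	48129895
chr22	p	0	14700000
chr22	q	14700000	51304566
chrX	p	0	60600000
chrX	q	60600000	155270560
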