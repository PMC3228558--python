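chrom	red	green	blue
chr1	153	102	0
chr2	102	102	0
chr3	153	153	30
chr4	204	0	0
chr5	255	0	0
chr6	255	0	204
chr7	255	204	204
chr8	255	153	0
chr9	255	204	0
chr10	255	255	0
chr11	204	255	0
chr12	0	255	0
chr13	53	128	0
chr14	0	0	204
chr15	102	153	255
chr16	153	204	255
chr17	0	255	255
chr18	204	255	255
chr19	153	0	204
chr20	204	51	255
chr21	204	153	255
chr22	102	102	102
chrX	153	153	153
chrY	204	204	204
chrM	204	204	153
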