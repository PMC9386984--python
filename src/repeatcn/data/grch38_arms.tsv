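chrom	start	end	arm
chr1	0	123400000	1p
chr1	123400000	248956422	1q
chr2	0	93900000	2p
chr2	93900000	242193529	2q
chr3	0	90900000	3p
chr3	90900000	198295559	3q
chr4	0	50000000	4p
chr4	50000000	190214555	4q
chr5	0	48800000	5p
chr5	48800000	181538259	5q
chr6	0	59800000	6p
chr6	59800000	170805979	6q
chr7	0	60100000	7p
chr7	60100000	159345973	7q
chr8	0	45200000	8p
chr8	45200000	145138636	8q
chr9	0	43000000	9p
chr9	43000000	138394717	9q
chr10	0	39800000	10p
chr10	39800000	133797422	10q
chr11	0	53400000	11p
chr11	53400000	135086622	11q
chr12	0	35500000	12p
chr12	35500000	133275309	12q
chr13	0	17700000	13p
chr13	17700000	114364328	13q
chr14	0	17200000	14p
chr14	17200000	107043718	14q
chr15	0	19000000	15p
chr15	19000000	101991189	15q
chr16	0	36800000	16p
chr16	36800000	90338345	16q
chr17	0	25100000	17p
chr17	25100000	83257441	17q
chr18	0	18500000	18p
chr18	18500000	80373285	18q
chr19	0	26200000	19p
chr19	26200000	58617616	19q
chr20	0	28100000	20p
chr20	28100000	64444167	20q
chr21	0	12000000	21p
chr21	12000000	46709983	21q
chr22	0	15000000	22p
chr22	15000000	50818468	22q
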