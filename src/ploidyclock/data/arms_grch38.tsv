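# GRCh38 autosome lengths and approximate centromere midpoints (bp).
# p arm: 1..cen_mid, q arm: cen_mid+1..length. Curated from UCSC hg38
# chromInfo and cytoband tables; centromere midpoints rounded to 0.1 Mb.
chrom	length	cen_mid
1	248956422	123400000
2	242193529	93900000
3	198295559	90900000
4	190214555	50000000
5	181538259	48800000
6	170805979	59800000
7	159345973	60100000
8	145138636	45200000
9	138394717	43000000
10	133797422	39800000
11	135086622	53400000
12	133275309	35500000
13	114364328	17700000
14	107043718	17200000
15	101991189	19000000
16	90338345	36800000
17	83257441	25100000
18	80373285	18500000
19	58617616	26200000
20	64444167	28100000
21	46709983	12000000
22	50818468	15000000
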