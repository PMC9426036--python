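# build=GRCh38
# Curated hotspot table: IDH1 codon R132 and IDH2 codon R172 missense
# variants on the canonical transcripts (both genes on the minus strand,
# so genomic ref/alt are the reverse complement of the coding change),
# plus the two canonical TERT promoter positions. Positions are 1-based.
gene	label	chrom	pos	ref	alts
IDH1	R132H	2	208248389	C	T
IDH1	R132L	2	208248389	C	A
IDH1	R132P	2	208248389	C	G
IDH1	R132C	2	208248390	G	A
IDH1	R132G	2	208248390	G	C
IDH1	R132S	2	208248390	G	T
IDH2	R172K	15	90088702	C	T
IDH2	R172M	15	90088702	C	A
IDH2	R172W	15	90088703	G	A
IDH2	R172G	15	90088703	G	C
IDH2	R172T	15	90088703	G	T
IDH2	R172S	15	90088701	C	A
TERT	C228T	5	1295113	G	A
TERT	C250T	5	1295135	G	A
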