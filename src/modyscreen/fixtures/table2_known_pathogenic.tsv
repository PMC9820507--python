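# Previously reported pathogenic / likely pathogenic MODY mutations (known,
# HGMD DM/DM? with QCI and/or ClinVar P/LP). The publication prints no genomic
# positions for these variants; POS values here are SYNTHETIC deterministic
# placeholders inside each gene's GRCh38 panel region, chosen for replay only.
# DIAGNOSIS is "CLASS:count" pairs separated by ";". CADD "<10" means below 10.
GENE	MODY	DBSNP	CHROM	POS	REF	ALT	PROTEIN_CHANGE	N	MAF	PENETRANCE	DIAGNOSIS	CADD	HGMD	QCI	CLINVAR	SIFT	POLYPHEN
HNF4A	1	rs1555817727	20	44356001	C	T	p.Arg312Cys	1	0.000035	100	T2DM:1	30	DM	P	LP	D	P.D
GCK	2	rs1375656631	7	44143501	C	T	p.Ala259Thr	3	0.000104	66.6	ND:1;T2DM:2	24.4	DM	P	P	D	Benign
GCK	2	rs104894005	7	44143511	C	G	p.Glu279Gln	1	0.000035	0	ND:1	22.2	DM	LP	P	T	Benign
HNF1A	3	rs137853238	12	120977601	G	A	p.Arg272His	1	0.000035	100	T2DM:1	31	DM	P	P	D	P.D
HNF1A	3	rs587778397	12	120977611	C	T	p.Arg177Trp	5	0.000174	20	ND:4;T2DM:1	25.7	DM	LP	VUS	T	P.D
HNF1A	3	rs371717826	12	120977621	C	G	p.Pro379Arg	3	0.000104	0	ND:3	26.7	DM	P	N/A	D	P.D
HNF1A	3	rs754729248	12	120977631	C	G	p.Pro379Ala	1	0.000035	0	ND:1	25	DM	VUS	P	D	P.D
KLF11	7	rs121912645	2	10042601	G	T	p.Ala347Ser	1	0.000035	0	ND:1	<10	DM	P	P	T	Benign
BLK	11	rs766934515	8	11491801	T	G	p.Val113Gly	5	0.000174	0	ND:5	29.9	DM?	LP	N/A	D	P.D
ABCC8	12	rs761862121	11	17392701	T	G	p.Lys889Thr	3	0.000104	0	ND:3	27.5	DM	P	VUS	D	P.D
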