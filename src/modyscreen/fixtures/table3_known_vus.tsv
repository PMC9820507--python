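# Previously reported HGMD DM/DM? variants of uncertain clinical significance
# (no P/LP in QCI or ClinVar) in the top 1% most deleterious (CADD Phred > 20).
# POS values are SYNTHETIC placeholders inside each gene's GRCh38 panel region
# (the publication prints no positions for these rows); replay use only.
GENE	MODY	DBSNP	CHROM	POS	REF	ALT	PROTEIN_CHANGE	N	MAF	PENETRANCE	DIAGNOSIS	CADD	HGMD	QCI	CLINVAR	SIFT	POLYPHEN
HNF4A	1	rs769007443	20	44356101	G	A	p.Gly64Arg	1	0.000035	0	ND:1	25.9	DM	VUS	N/A	D	P.D
HNF4A	1	rs371124358	20	44356111	G	A	p.Arg310Gln	1	0.000035	100	T2DM:1	23.5	DM	VUS	VUS	T	Benign
HNF4A	1	rs377151067	20	44356121	G	A	p.Val404Ile	1	0.000035	100	T2DM:1	22.8	DM	VUS	N/A	T	Benign
GCK	2	rs193922285	7	44143601	C	A	p.Met462Ile	5	0.000174	40	ND:3;T2DM:2	22.9	DM	VUS	VUS	T	Benign
HNF1A	3	rs201095611	12	120977701	G	A	p.Ala161Thr	6	0.000209	16.67	ND:5;T1DM:1	27.3	DM	VUS	VUS	D	P.D
HNF1A	3	rs867576513	12	120977711	T	C	p.Met283Thr	6	0.000209	33.3	ND:4;T2DM:2	25.6	DM	VUS	N/A	D	P.D
HNF1A	3	rs368683806	12	120977721	G	A	p.Gly415Arg	1	0.000035	0	ND:1	31	DM	VUS	VUS	D	P.D
HNF1A	3	rs577078110	12	120977731	C	A	p.His505Asn	2	0.000070	0	ND:2	26.3	DM	VUS	N/A	D	P.D
HNF1A	3	rs202039659	12	120977741	A	G	p.His514Arg	11	0.000383	27.2	ND:8;T2DM:3	24.8	DM	VUS	VUS	D	P.D
PDX1	4	rs753249965	13	27920101	G	A	p.Gly55Asp	3	0.000104	0	ND:3	23.7	DM	VUS	N/A	D	Benign
HNF1B	5	rs113042313	17	37686701	C	T	p.Gly370Ser	1	0.000035	0	ND:1	21	DM	VUS	N/A	T	Benign
BLK	11	rs368427116	8	11491901	C	T	p.Thr270Met	5	0.000174	0	ND:5	25.4	DM	VUS	N/A	T	P.D
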