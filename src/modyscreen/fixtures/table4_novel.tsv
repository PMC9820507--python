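# Potentially novel fully penetrant MODY-causing mutations: no HGMD DM/DM?
# record, ClinVar not P/LP, CADD Phred > 20, 100% disease penetrance. All
# carriers were classified as T2DM. CHROM:POS are the published GRCh38
# coordinates. "-" means not available.
GENE	MODY	CHROM	POS	DBSNP	REF	ALT	PROTEIN_CHANGE	N	MAF	PENETRANCE	DIAGNOSIS	CADD	GNOMAD_AF	SIFT	POLYPHEN
HNF4A	1	20	44418486	-	T	C	p.Met237Thr	1	0.000035	100	T2DM:1	26.2	-	D	P.D
HNF4A	1	20	44424203	rs776656815	C	G	p.Leu360Val	1	0.000035	100	T2DM:1	22.8	0.0000239	D	Benign
GCK	2	7	44145572	-	A	T	p.Met393Lys	1	0.000035	100	T2DM:1	26.2	-	D	Benign
HNF1A	3	12	120993541	-	G	A	p.Gly183Glu	1	0.000035	100	T2DM:1	26.1	-	D	P.D
HNF1A	3	12	120979082	-	A	T	p.Glu105Val	2	0.000070	100	T2DM:2	25.2	-	D	Benign
HNF1A	3	12	120999538	-	C	T	p.Ser591Phe	1	0.000035	100	T2DM:1	24.1	-	D	P.D
PDX1	4	13	27924690	rs1357043267	G	C	p.Glu281Gln	3	0.000104	100	T2DM:3	23.1	0.000119	D	Benign
HNF1B	5	17	37744622	-	G	A	p.Thr88Ile	1	0.000035	100	T2DM:1	25.4	-	D	Benign
HNF1B	5	17	37731607	rs755951130	T	C	p.Asn345Asp	1	0.000035	100	T2DM:1	22.6	0.0000081	T	Benign
NEUROD1	6	2	181678436	-	G	A	p.Thr142Ile	1	0.000035	100	T2DM:1	28.2	-	D	P.D
KLF11	7	2	10046337	-	A	G	p.Asp77Gly	1	0.000035	100	T2DM:1	27.9	-	D	P.D
KLF11	7	2	10048367	-	C	T	p.Pro344Ser	1	0.000035	100	T2DM:1	23.2	-	D	P.D
KLF11	7	2	10046240	-	A	T	p.Met45Leu	1	0.000035	100	T2DM:1	20.1	-	T	Benign
CEL	8	9	133070564	rs766487195	G	A	p.Gly467Arg	1	0.000035	100	T2DM:1	26.1	0.0000080	D	P.D
CEL	8	9	133064413	rs748643667	G	A	p.Val29Met	1	0.000035	100	T2DM:1	25.3	0.0000040	D	P.D
CEL	8	9	133066888	rs773198000	C	G	p.Ser243Arg	1	0.000035	100	T2DM:1	22.9	0.0000242	D	P.D
CEL	8	9	133069087	-	A	G	p.Thr375Ala	1	0.000035	100	T2DM:1	22.3	-	D	Benign
BLK	11	8	11554800	rs775313404	A	G	p.Tyr177Cys	1	0.000035	100	T2DM:1	29.4	0.0000119	D	P.D
ABCC8	12	11	17404576	rs769818698	C	T	p.Val1165Met	2	0.000070	100	T2DM:2	23.1	0.0000955	D	Benign
ABCC8	12	11	17427908	-	C	T	p.Gly692Glu	1	0.000035	100	T2DM:1	22.7	-	T	Benign
KCNJ11	13	11	17387440	-	G	T	p.Gln131Lys	1	0.000035	100	T2DM:1	24.2	-	T	P.D
KCNJ11	13	11	17387761	rs867211548	C	T	p.Val24Ile	1	0.000035	100	T2DM:1	20.7	-	T	Benign
APPL1	14	3	57269587	-	A	T	p.Asn677Ile	1	0.000035	100	T2DM:1	21.4	-	T	Benign
RFX6	candidate	6	116922098	rs1485759457	G	A	p.Val462Met	1	0.000035	100	T2DM:1	26.1	-	D	P.D
RFX6	candidate	6	116927531	rs762356403	C	T	p.Ser797Leu	1	0.000035	100	T2DM:1	22.9	0.0000081	D	Benign
RFX6	candidate	6	116924786	-	A	C	p.Asn558Thr	1	0.000035	100	T2DM:1	22.4	-	T	Benign
NKX6-1	candidate	4	84498074	-	G	A	p.Ser52Phe	2	0.000070	100	T2DM:2	24.2	-	D	Benign
NKX6-1	candidate	4	84498145	rs369821275	C	G	p.Met28Ile	2	0.000070	100	T2DM:2	23.5	0.0000525	D	Benign
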