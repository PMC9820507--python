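# MODY 16-gene panel, GRCh38, 0-based half-open intervals.
# Canonical gene spans (UCSC-style) with small padding; column 5 is the MODY
# subtype number, or "candidate" for the two candidate genes RFX6 and NKX6-1.
20	44355700	44434600	HNF4A	1
7	44143200	44198200	GCK	2
12	120977300	121002600	HNF1A	3
13	27919800	27926400	PDX1	4
17	37686400	37745100	HNF1B	5
2	181668200	181681000	NEUROD1	6
2	10042300	10054700	KLF11	7
9	133061900	133072000	CEL	8
7	127610200	127618200	PAX4	9
11	2159700	2161300	INS	10
8	11491500	11564700	BLK	11
11	17392400	17476900	ABCC8	12
11	17385200	17389400	KCNJ11	13
3	57227500	57274100	APPL1	14
6	116891200	116947600	RFX6	candidate
4	84491000	84500100	NKX6-1	candidate
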