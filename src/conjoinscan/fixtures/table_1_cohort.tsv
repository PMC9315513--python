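sample_id	age	sex	phenotype	bm_blasts_pct	translocations	dna_index	steroid_response	mrd_group
#8	16	M	BII	86	NEG	1	PGR	HR
#11	15	M	BII	80	NEG	1	PGR	HR
#12	3	F	BI	73	NEG	1	PGR	HR
#13	4	F	BIII	78	NEG	1	PGR	HR
#15	9	F	BII	74	NEG	1	PGR	HR
#16	11	M	BIII	90	NEG	1	PGR	HR
#6	1	M	BII	94	NEG	1	PGR	SR
#7	5	M	BII	70	NEG	1	PGR	SR
#9	15	M	BII	94	NEG	1	PGR	SR
#14	8	M	BII/BIII	90	NEG	1	PGR	SR
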