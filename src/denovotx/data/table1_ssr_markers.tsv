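# 23 successfully amplified EST-SSR loci with polymorphism screening status
# status: YES = potentially polymorphic, NO = monomorphic, NULL = null alleles
locus_id	gene_id	motif	n_repeats	status
MR5	Unigene7776_All	TC	6	YES
MR7	Unigene4546_All	CT	6	NULL
MR8	Unigene9496_All	TC	6	YES
MR13	Unigene26276_All	TC	7	YES
MR14	Unigene12899_All	CT	8	YES
MR18	Unigene54607_All	TC	10	YES
MR20	Unigene9630_All	TG	13	NULL
MR23	Unigene51169_All	TC	23	NO
MR24	Unigene2731_All	AGC	5	NULL
MR31	Unigene16282_All	TTG	5	NO
MR32	Unigene10567_All	ACC	5	YES
MR39	Unigene7685_All	ATT	6	NO
MR40	Unigene18380_All	TCC	6	NO
MR41	Unigene11347_All	TCA	7	YES
MR47	Unigene9912_All	GGA	7	YES
MR51	Unigene826_All	CTT	7	YES
MR52	Unigene9209_All	TCC	7	YES
MR53	Unigene33994_All	CAT	7	YES
MR55	Unigene35088_All	CCT	6	YES
MR56	Unigene9209_All	CCT	9	YES
MR57	Unigene33873_All	AGG	13	NULL
MR58	Unigene51169_All	TCT	24	YES
MR59	Unigene1832_All	ATTT	5	NULL
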