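# Distribution of repetitive elements across the transcriptome
# bp_printed preserves the source table's typography (including the
# misplaced commas in two rows); bp is the interpreted integer value.
# Percentages are of 57,891,795 bp of non-ambiguous sequence.
element_class	n_elements	bp_printed	bp	percent
Retroelements	728	76,814	76814	0.13
Penelope	3	165	165	0.00
LINEs	359	32, 845	32845	0.06
LTR elements	369	43, 969	43969	0.08
DNA transposon	124	13,313	13313	0.02
Unclassified	11	554	554	0.00
Total interspersed repeats		90,681	90681	0.16
Satellites	6	675	675	0.00
Simple repeats	8332	31,8339	318339	0.55
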