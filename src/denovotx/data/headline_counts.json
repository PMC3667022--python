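{
  "n_unigenes": 102230,
  "nr_hits": 24476,
  "novel_coding_predictions": 7595,
  "coding_total": 32334,
  "repeat_bp": 756405,
  "non_ambiguous_bp": 57891795,
  "simple_repeat_bp": 318339,
  "simple_repeat_loci": 8332
}
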