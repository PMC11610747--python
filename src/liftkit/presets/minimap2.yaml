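name: minimap2
selection:
  mapq_min: 5
  aln_score_min: 40
  clip_frac_max: 0.05
scoring:
  match: 2
  mismatch: 4
  gap_open: 4
  gap_extend: 2
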