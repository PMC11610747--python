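name: bwa-mem
selection:
  mapq_min: 30
  aln_score_min: 100
  clip_frac_max: 0.05
scoring:
  match: 1
  mismatch: 4
  gap_open: 6
  gap_extend: 1
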