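name: bowtie2
selection:
  mapq_min: 10
  aln_score_min: -10
  clip_frac_max: 0.05
scoring:
  match: 0
  mismatch: 6
  gap_open: 5
  gap_extend: 3
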