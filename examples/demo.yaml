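# One-command demo: a 60 kb genome with two genes, 30x single-end 100 bp
# reads, 1% substitution errors, 0.1% SNP divergence from the reference.
simulate:
  genome_len: 60000
  gene_intervals: [[10000, 15000], [30000, 38000]]
  snp_rate: 0.001
  error_rate: 0.01
  read_len: 100
  coverage: 30.0
  layout: single
  seed: 42
extract:
  flank: 50
  min_identity: 95
correct:
  minor_count: 3
  minor_frac: 0.02
  min_depth_for_frac: 100
  row_error_frac: 0.02
  out_threshold: 0.2
  max_passes: 8
  seed: 42
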