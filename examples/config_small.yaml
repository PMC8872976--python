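# Small end-to-end smoke configuration (fast; rg estimates are noisy at
# this scale — use the package defaults for better-calibrated output).
simulation:
  n: 2000
  m: 3000
  n_chrom: 10
  bp_spacing: 150000
  ld_block_size: 4
  ld_copy_prob: 0.9
  seed: 11
  n_external: 8000
  external_traits: [external_md]
estimation:
  n_blocks: 200
  jackknife_seed: 1234
outdir: phenocomb_small_out
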