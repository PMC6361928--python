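# Full synthetic GWEIS study: 2,000 samples x 5,000 SNPs, additive h2 10%,
# pure-interaction variance 5%, SLE-like count exposure averaging 2 events.
seed: 1
out_prefix: demo
simulate:
  n_samples: 2000
  n_snps: 5000
  n_causal_additive: 100
  n_causal_gxe: 100
  var_additive: 0.10
  var_gxe: 0.05
  exposure_mean: 2.0
  exposure_h2: 0.0
  ld_block_size: 5
  ld_rho: 0.2
gweis:
  robust_variant: HC0
prs:
  p_threshold: 1.0
  clump_r2: 0.1
  clump_window_kb: 250
evaluate:
  n_perm: 300
  discovery_fraction: 0.5
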