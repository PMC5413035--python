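# Small synthetic end-to-end run: generate a landscape and genotypes,
# optimize the slope resistance model, simulate novel-allele spread.
seed: 7
scenario:
  continuity_class: continuous_linear
  n_rows: 48
  n_cols: 48
  cell_size: 100.0          # metres
  slope_threshold: 30.0     # degrees; habitat = escape terrain
  n_individuals: 120
  n_loci: 12
  alleles_per_locus: 6
  burn_in_years: 120
  true_curve: {family: gaussian, r_max: 100, x_opt: 50, x_sd: 20}
optimization:
  n_iter: 100
  n_perm: 199
  alpha: 0.05
  ladder:
    slope:
      kind: continuous
      families: [monotonic_positive, monotonic_negative, gaussian]
      r_max: [10, 100]
      r_exp: [0.25, 1, 4]
      x_opt: [30, 50, 70]
      x_sd: [20]
simulation:
  s: 0.3                    # strong selection
  scenario: novel
  years: 50
  n_replicates: 10
  d_max_quantile: 0.25
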