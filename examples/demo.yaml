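# Full-scale demo screen: the default design made explicit.
simulation:
  n_compounds: 590
  class_proportions:
    btk_inhibitor: 0.03
    pi3k_inhibitor: 0.08
    cytotoxic: 0.25
    collateral_sensitive: 0.005
    inert: 0.635
  doses: [100.0, 1000.0]
  n_replicates: 2
  cells_seeded_per_well: 10000
  cv_well_noise: 0.10
  fields_per_well: 5
  rng_seed: 7
hit_threshold_pct: 20.0
ratio_threshold: 10.0
use_images: false
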