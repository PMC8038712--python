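# Default pipeline configuration; any key may be overridden.
alpha: 0.05
replicate_handling: average
k_components: 4
min_prominence: 0.1
search_halfwidth: 15.0
preprocess:
  baseline: rubberband
  normalization: area
  sg_half_width: 1
  sg_polyorder: 2
  derivative_order: 2
  regions:
  - - 2800
    - 3000
  - - 1500
    - 1800
  - - 900
    - 1200
simulate:
  scenario: coriell
  n_samples_per_group: 4
  replicates_per_sample: 3
  spacing: 2.0
  noise_sd: 0.002
  amplitude_cv: 0.08
  seed: 0
input:
  spectra_csv: null
  metadata_csv: null
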