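# Synthetic demonstration run: a selection-driven community in the
# two-group x four-stage x four-pond design, scaled so the full pipeline
# finishes in well under ten minutes on one CPU.
outdir: aquacomm_demo
seed: 42
scenario:
  n_taxa: 300
  n_ponds_per_group: 4
  n_stages: 4
  depth: 4000
  regime: selection
  selection_width: 0.1
  trait_rate: 0.05
  nitrate_amplitude_ratio: 2.0
  noise_sd: 0.02
params:
  n_null: 99
  permanova_permutations: 199
  rda_permutations: 99
  titan_permutations: 100
  titan_bootstrap: 40
  robustness_reps: 50
  cohesion_null: 100
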