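# Demo configuration: a small genome with retention, excision errors,
# old-MAC contamination and pre-existing parental error junctions.
# Run:  iespipe run-all --config configs/demo.yaml --seed 11 --out-dir demo_out
sim:
  n_scaffolds: 2
  scaffold_len: 10000
  n_ies: 20
  read_len: 100
  coverage: 60
  retention_prob: 0.3
  error_rate: 0.2
  error_class_mix:
    PARTIAL_INTERNAL: 0.5
    PARTIAL_EXTERNAL: 0.1
    INTERNAL: 0.15
    EXTERNAL: 0.15
    OVERLAPPING: 0.1
  old_mac_fraction: 0.1
  parental_error_junctions: 5
  seed: 11

length_model:
  min_len: 26
  period: 10.2
  peak_weights: [0.30, 0.01, 0.25, 0.20, 0.14, 0.10]
  peak_sd: 1.0
  max_len: 150

mapper:
  k: 12
  min_anchor: 12

retention:
  alpha: 0.05
  policy: any            # "any" or "both" boundaries significant
  fully_excised_threshold: 0.025
  bin_width: 0.025

errors:
  min_shift: 3           # exclude alternative boundaries at <= 2 bp
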