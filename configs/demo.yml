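# Small demonstration run: 4 subjects, reduced voxel count, full 12-min scan
# geometry. Usable as: neuroentropy run configs/demo.yml -o results/demo
generator:
  seed: 42
  n_networks: 9
  voxels_per_network: 8
  n_timepoints: 240
  sampling_interval: 3.0
  infusion_onset: 120
  infusion_duration: 20
cohort:
  n_subjects: 4
analysis:
  mode: amplitude
  n_bins: 10
  edges_strategy: pooled
  window_len: 20
  step: 1
  threshold: 0.5
  threshold_sweep: [0.3, 0.4, 0.5, 0.6]
  alpha_family: 0.05
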