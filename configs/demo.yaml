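# Demo configuration: small synthetic network, full analysis.
# Run:  coshnet run --config configs/demo.yaml --seed 3 --out results/demo
network:
  source: synthetic
  stats:
    n_vessels: 30
    bounding_box: [160.0, 160.0, 130.0]
    n_converging: 7
  measurement_fraction: 0.4
  measurement_noise: 50.0      # μm/s
inflow:
  mode: constant               # or: uniform, with value: [0.5, 0.7]
  value: 0.6
voxel_spacing: 2.0             # μm (1.0 for production runs)
solver:
  t_end: 5.0                   # s (10.0 for production runs)
  averaging_window: 1.5        # s
oxygen: {}                     # OxygenParameters overrides, e.g. M0: 6.0e-4
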