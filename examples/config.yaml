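# Pipeline configuration for `rotorrisk run-all --config examples/config.yaml`.
# A compact synthetic facility; omit `simulation` keys to get the full
# 110-turbine / 11-month / 10,000-approach study-scale defaults.
seed: 1
paths:
  output_dir: scratch/pipeline_out
  # To analyse real data instead of the simulate stage's output, point
  # these at CSVs in the documented schemas and skip `simulate`:
  # tracks: my_tracks.csv
  # turbines: my_turbines.csv
criteria:
  inner_radius: 150.0        # m; "within 150 m" approach filter
  outer_radius: 350.0        # m
  inner_height: 200.0        # m, centred on the hub, clipped at ground
  outer_height: 400.0        # m
  time_to_collision_threshold: 10.0   # s
  confidence_threshold: 0.90
simulation:
  n_turbines: 20
  n_siemens: 8
  total_approaches: 1200
model:
  n_chains: 3
  n_iterations: 3000
  burn_in: 500
  thin: 2
summary:
  safer_threshold: 0.95
  riskier_threshold: 0.05
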