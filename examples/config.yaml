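# Full-pipeline example: two simulated populations compared end to end.
# Run with:  melanotrack report --config examples/config.yaml --out report/
seed: 1
settings:
  frame_interval: 0.5   # seconds
  n_frames: 601
  pixel_size: 0.16      # μm
nucleus_center: [0.0, 0.0]
populations:
  - label: control
    simulate:
      - {process: brownian, D: 2.5e-4, count: 60}
      - {process: brownian_drift, D: 2.5e-4, V: 0.04, heading: 0.8, count: 15}
  - label: depleted
    simulate:
      - {process: brownian, D: 2.5e-4, count: 30}
      - {process: brownian_drift, D: 2.5e-4, V: 0.06, heading: -0.4, count: 45}
msd:
  max_lag_fraction: 0.25
  n_lags: 10
classification:
  tau_S: 5.0            # seconds
  tau_L: 40.0
  q_low: 0.50
  q_high: 0.95
  n_reference: 2000
  D_reference: 0.01
compare:
  - [control, depleted]
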