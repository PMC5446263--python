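# Minimal cascade, fixed 4-min pulse width, 64-min period (one member of
# the non-compensated family; vary period_min for the full scan).
# Run: gnrhsim simulate --config experiments/minimal_frequency_scan.yaml --out tc.csv
model: minimal
protocol:
  amplitude_M: 1.0e-7
  width_min: 4
  period_min: 64
  horizon_min: 1024
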