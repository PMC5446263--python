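# Frequency scan at 8x internalization: Ca2+ optimum at 30-min period.
# Run: gnrhsim scan-frequency --config experiments/frequency_scan_8x.yaml --out aucs.csv --summary summary.json
model: network
protocol:
  amplitude_M: 1.0e-7
  width_min: 5
  horizon_min: 960
scan_periods: [15, 30, 60]
network_params:
  int_mult: 8.0
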