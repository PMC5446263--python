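# Constant-stimulation concentration scan at 0.5x internalization (the
# regime where the co-operative gate's dose response is bell-shaped).
# Run: gnrhsim scan-dose --config experiments/dose_scan.yaml --out aucs.csv
model: network
protocol:
  horizon_min: 960
scan_concentrations: [1.0e-11, 1.0e-10, 1.0e-9, 1.0e-8, 1.0e-7, 1.0e-6]
network_params:
  int_mult: 0.5
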