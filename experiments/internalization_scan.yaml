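# Pulse-frequency scans at each internalization multiplier (Ca2+ and PLC
# AUC shapes; bell threshold at 4x).
# Run: gnrhsim scan-internalization --config experiments/internalization_scan.yaml --out aucs.csv
model: network
protocol:
  amplitude_M: 1.0e-7
  width_min: 5
  horizon_min: 960
scan_periods: [5, 15, 30, 60, 120, 240, 480]
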