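# Co-operative-gate reporter under 15-min pulses, negligible feedback
# (the interior-period condition of the frequency bell).
# Run: gnrhsim reporter --config experiments/reporter_coop.yaml --gate COOP --out reporter.csv
model: network
protocol:
  amplitude_M: 1.0e-7
  width_min: 5
  period_min: 15
  horizon_min: 960
network_params:
  int_mult: 0.001
gate:
  mode: COOP
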