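# Reference pulse response: 5-min pulses of 1e-7 M GnRH, 60-min period.
# Run: gnrhsim simulate --config experiments/pulse_response.yaml --out tc.csv
model: network
protocol:
  amplitude_M: 1.0e-7
  width_min: 5
  period_min: 60
  horizon_min: 960
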