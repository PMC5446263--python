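# Single-cell population for MI estimation: 8 GnRH levels (3-bit input),
# log-normal heterogeneity in receptor and ERK totals.
# Run: gnrhsim mi simulate --config experiments/population_mi.yaml --seed 1 --out cells.csv
#      gnrhsim mi estimate --in cells.csv --bins 16 --boot 200
model: network
population:
  n_cells: 20
  parameter_cvs: {Rtot: 0.3, ERKtot: 0.3}
  noise_sd: 0.001
rtol: 1.0e-6
atol: 1.0e-9
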