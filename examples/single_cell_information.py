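"""Mutual information between GnRH concentration and single-cell output.

Simulates two synthetic cell populations with identical mean
dose-response curves but different cell-to-cell variability, estimates
the stimulus-response mutual information for each, and shows that the
noisier population transmits fewer bits of the 3-bit (8-level) input.
"""
from gnrhsim import PopulationSpec, estimate_mi, input_entropy, simulate_population
from gnrhsim.infotheory import hill_response_model

levels = tuple(10.0 ** e for e in (-11, -10.5, -10, -9.5, -9, -8.5, -8, -7))
print(f"input entropy: {input_entropy(len(levels)):.1f} bits")
for label, cv in (("low variability ", 0.15), ("high variability", 0.6)):
    spec = PopulationSpec(stimulus_levels=levels, n_cells=300,
                          parameter_cvs={"gain": cv}, seed=1)
    samples = simulate_population(spec, response_model=hill_response_model())
    est = estimate_mi(samples, n_boot=100)
    print(f"{label} (CV {cv}): MI = {est.mi_bits_corrected:.2f} bits "
          f"[{est.ci_low:.2f}, {est.ci_high:.2f}]")
print("\nSame average dose-response, very different information transfer: "
      "population\naverages hide how reliably individual cells sense the "
      "stimulus.")
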