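# gnrhsim

Simulation and analysis of pulsatile GnRH signaling in pituitary
gonadotropes: how cells decode the *frequency* of a hormone pulse train,
and how reliably single cells report the hormone concentration they see.

GnRH (gonadotropin-releasing hormone) reaches the pituitary as short
secretory pulses, and its effects depend on pulse frequency — constant
stimulation can even suppress the responses that pulses sustain. The type I
mammalian GnRH receptor lacks a C-terminal tail and does not rapidly
desensitize, so the interesting question is where frequency decoding and
desensitization actually live. This package implements, as tested
simulators:

- **`gnrhsim.pulses`** — square-wave pulse protocols, exact input
  integrals, and *compensated* protocol families in which pulse width
  shrinks as frequency rises so every member delivers the same total input.
- **`gnrhsim.minimal`** — a three-effector Michaelis–Menten cascade
  (stimulus → E1\* → E2\*, E3\*) with fast E1/E3 and a ≥10-fold slower E2.
  For d/dt of each active effector Ei\*:

      dEi*/dt = drive · kact_i (Ti − Ei*)/(Kact_i + Ti − Ei*)
                − Vinact_i Ei*/(Kinact_i + Ei*)

  Fast effectors integrate the input (AUC ∝ input integral); the slow one
  responds to frequency even at fixed input integral.
- **`gnrhsim.network`** — a 13-state ODE model of the GnRH receptor
  network: ligand binding, agonist-induced receptor internalization and
  saturable recycling (the only upstream negative feedback), PLC, cytoplasmic
  Ca²⁺ with a slow PLC-driven inactivation of the release gain, a collapsed
  Raf/MEK/ERK tier with nucleocytoplasmic ppERK shuttling, a four-pool
  NFAT phosphorylation/localization cycle driven by calcineurin, and
  nuclear Egr1. Internalization/recycling strength is exposed as
  multipliers (`int_mult`, `rec_mult`) of the base rates.
- **`gnrhsim.gates`** — five transcriptional logic gates driven by nuclear
  ppERK (E) and the NFAT nuclear fraction (N): `ERK_DT`, `NFAT_DT`, `AND`,
  `OR` (instantaneous Hill combinations) and `COOP`, a sequential
  co-operative promoter in which NFAT binds first (slow) and the
  ERK-dependent factor second (fast), with transcription from the
  doubly-bound state. COOP is a coincidence detector of the slow and fast
  branches and produces bell-shaped frequency responses without negative
  feedback.
- **`gnrhsim.scan`** — frequency/dose scanning with 960-min AUC readouts,
  optimum-period identification and monotonic-vs-bell shape classification.
- **`gnrhsim.infotheory`** — synthetic single-cell populations (log-normal
  parameter heterogeneity) and a mutual-information estimator
  (quantile-binned plug-in MI with jackknife bias correction and bootstrap
  CI). With eight equiprobable GnRH levels the input carries
  log₂ 8 = 3 bits; MI measures how many of them one cell's response
  transmits.

## Worked example

```python
from gnrhsim import NetworkParams, frequency_scan, optimal_period

params = NetworkParams()
for mult in (1, 8, 16):
    scan = frequency_scan(params.with_multipliers(int_mult=mult),
                          periods=[15, 30, 60], channels=("Ca",),
                          rtol=1e-6, atol=1e-9)
    best, _ = optimal_period(scan, "Ca")
    aucs = ", ".join(f"{T:.0f} min: {a:.0f}"
                     for T, a in zip(scan.axis, scan.channel("Ca")))
    print(f"int_mult {mult:>2}x  Ca AUC ({aucs})  ->  optimum {best:.0f} min")
```

prints

```
int_mult  1x  Ca AUC (15 min: 784, 30 min: 517, 60 min: 316)  ->  optimum 15 min
int_mult  8x  Ca AUC (15 min: 284, 30 min: 373, 60 min: 284)  ->  optimum 30 min
int_mult 16x  Ca AUC (15 min: 120, 30 min: 194, 60 min: 228)  ->  optimum 60 min
```

Each row scans 5-min pulses of 10⁻⁷ M GnRH at 15/30/60-min periods and
integrates cytoplasmic Ca²⁺ over 960 min: at the fitted internalization
rate (1×) the highest frequency wins, but as internalization strengthens
(8×, 16×) the optimum shifts to sparser pulses — upstream negative feedback
turns the frequency response bell-shaped. More narrative scripts live under
`examples/` (one per capability), and `experiments/` holds one run
configuration per figure-level analysis for the CLI:

```bash
gnrhsim simulate --config experiments/pulse_response.yaml --out tc.csv
gnrhsim scan-frequency --config experiments/frequency_scan_8x.yaml \
        --out aucs.csv --summary summary.json
gnrhsim mi simulate --config experiments/population_mi.yaml --seed 1 --out cells.csv
gnrhsim mi estimate --in cells.csv --bins 16 --boot 200
```

## Layout

```
src/gnrhsim/      library (pulses, minimal, network, gates, scan,
                  infotheory, config, io, cli)
tests/            pytest suite incl. end-to-end acceptance checks
examples/         narrative scripts, one per capability
experiments/      one CLI run configuration per figure-level analysis
scripts/          acceptance + calibration audit scripts
docs/methods.md   model description, assumptions, parameter rationale
```
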