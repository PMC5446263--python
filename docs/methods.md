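# Methods

This note documents the models in `gnrhsim`: their equations and
assumptions, the parameters that matter and why they have the values
they do, what the synthetic data emulate (and do not), and the
numerical choices. Units are minutes and µM throughout; the stimulus
is molar GnRH.

## Pulse protocols

A protocol is a square wave: concentration `amplitude` for `width`
minutes at the start of every `period`, `baseline` (default 0) in
between, pulses starting at t = 0 (traces rise immediately at
stimulus onset). `width == period` encodes constant stimulation.
Input integrals are computed in closed form, counting partial trailing
pulses; compensated families (`width = duty * period`) require the
horizon to be a common multiple of all periods so the equal-integral
guarantee is exact. Non-square shapes (ramps, physiological secretion
profiles) and stochastic pulse timing are out of scope.

## Minimal cascade

Three effectors with Michaelis–Menten activation/inactivation; the
stimulus enters E1's activation as a dimensionless 0/1 multiplier
(amplitude is folded into `kact_1`, because a single input level
cannot identify a separate scale). E2 and E3 are driven by E1\*.
Defaults (totals 1 a.u.):

| effector | kact | Kact | Vinact | Kinact | character |
|---|---|---|---|---|---|
| E1 | 10 | 50 | 100 | 50 | fast, near-linear, low occupancy |
| E2 | 3.2 | 2.0 | 0.28 | 2.0 | slow (relaxation ≈ 5–10 min effective) |
| E3 | 110 | 50 | 100 | 50 | fast, near-linear, driven by E1\* |

The fast effectors run at low fractional occupancy with large Michaelis
constants, which makes them effectively linear time-invariant filters:
their AUC is proportional to the input integral (straight line through
the origin versus pulse frequency in non-compensated scans; flat across
compensated families). E2's activation saturates in the pool while its
drive is weak, so long pulses waste input once E2 approaches its total,
and sustained low-duty drive holds E2 near a working point that brief,
frequent pulses maintain more efficiently: in a compensated family E2's
AUC strictly increases with frequency. With these (or any)
Michaelis–Menten kinetics the non-compensated E2 curve is increasing and
*saturating* — per-pulse responses are linear until pulses overlap, and
overlap can only blunt them — so nonlinearity is asserted as a >20 %
drop in per-pulse yield across the frequency range, not as convexity.

The fast/slow contract (E1, E3 at least 10-fold faster than E2) is
enforced at construction, using the linearized relaxation time at the
half-active state with the drive set to E1's steady active level.

## Receptor network

Thirteen states: three receptor pools (free surface, occupied surface
HR, internalized), active PLC, the Ca²⁺ release gate, cytoplasmic
Ca²⁺, cytoplasmic and nuclear ppERK, four NFAT pools, nuclear Egr1.
Receptor and NFAT totals are conserved exactly by construction; ligand
is a bath (no depletion) with instantaneous washout between pulses.

Topology and key choices:

- **Binding/trafficking.** kon = 5·10⁸ /M/min, koff = 1 /min
  (K_d = 2 nM, so 10⁻⁷ M pulses give ~98 % occupancy; binding
  equilibrates in seconds–minutes, and occupancy collapses within
  minutes of pulse end). Occupied receptor internalizes at
  `int_mult * 0.012` /min. Recycling is **saturable** — Michaelis–Menten
  in the internalized pool (half-saturation 0.15 of total), normalized
  so a fully internalized pool recycles at `rec_mult * 0.006` /min.
  Saturation separates two regimes the data demand simultaneously:
  small internalized pools (physiological rates, long inter-pulse
  intervals) recover quickly and completely, so internalization has
  negligible effect at 120-min periods, while large pools (sustained
  stimulation, high multipliers) recover at a capped rate, so constant
  stimulation desensitizes strongly. With linear recycling one rate
  constant would have to serve both regimes and cannot.
- **PLC.** First-order activation by HR (1.2 /µM/min) and deactivation
  (1.2 /min): τ under a minute, steady level ≈ HR/(HR+1).
- **Ca²⁺.** Leak (0.04 µM/min) and clearance (0.5 /min) set the 0.08 µM
  baseline. Release is a steep Hill of PLC (K 0.17 µM, h 4) times a
  slow inactivation gate `h`: the gate relaxes with τ = 30 min toward
  a PLC-dependent target that falls from 1 toward a floor of 0.30 past
  K = 0.14 µM, with an additional steep drop (27 % past 0.47 µM, h 8)
  near full PLC activation. This gate is a lumped, phenomenological
  stand-in for IP₃-receptor fast inactivation and store depletion — an
  *incoherent feed-forward* element (PLC both drives and curbs release).
  It is load-bearing: because the gate is slow it averages over pulse
  trains (pulses ride at high gain) while constant stimulation settles
  at the inactivated steady level, and its falling steady-state branch
  is the only mathematically possible source of the non-monotonic
  dose-responses downstream — every other steady state in the network
  is monotone in stimulus, and the transcription gates are monotone
  systems, so without a declining branch no gate output could peak at
  sub-maximal concentration. AUC readouts use the raw, non-baseline-
  subtracted Ca²⁺ trace (recorded in output metadata).
- **ERK.** A single phosphorylation stage stands in for Raf/MEK/ERK;
  the drive is a product of a steep PLC term (K 0.40 µM, h 5 —
  multi-step kinase cascades behave ultrasensitively) and a Ca²⁺ term
  (K 1.3 µM, h 3 — conventional PKC needs both DAG, represented by
  PLC, and Ca²⁺). ppERK shuttles into the nucleus (0.1 /min) and
  leaves by export + dephosphorylation (0.05 + 0.05 /min, τ ≈ 10 min):
  nuclear ppERK is still "rapidly reversed" (off half-time ≈ 9 min)
  but partially integrates pulse trains, which downstream gates exploit.
- **NFAT.** Four pools (cytoplasmic/nuclear × phosphorylated/de-),
  calcineurin activity a Hill of Ca²⁺ with K = 1.8 µM, h = 4. The high
  K places constant-stimulation Ca²⁺ plateaus (≈0.7–1 µM) low on the
  curve while 1.5–2 µM pulse spikes saturate it, so time-averaged
  calcineurin activity is *higher* under short-period pulses than under
  constant stimulation — the NFAT arm of the coincidence detection.
  (A coefficient of 2–3 is the textbook choice; 4 is used here because
  with a shallower curve the pulse/constant contrast is too weak to
  carry the bell-shaped gate responses.) Import of dephosphorylated
  NFAT is slow (0.015 /min) and export (rephosphorylation 0.06 /min
  then export 0.08 /min) gives an off half-time over 20 min, so the
  nuclear fraction accumulates across pulses and does not return to
  baseline at 30-min intervals.
- **Egr1.** Synthesis proportional to nuclear ppERK (0.25 /min),
  first-order loss (0.02 /min): the ERK-driven immediate-early readout.

The 120+ rate constants of the original wet-lab-trained formulation are
not public; these defaults were calibrated (and are re-audited by
`scripts/calibrate_network.py`) against the target ordinal behaviors:
Ca²⁺ optimum period 15/30/60 min at 1×/8×/16× internalization; first
bell-shaped Ca²⁺ frequency response at 4× on the 0.03125×–32× ladder
with PLC monotonic throughout; the pulsatility-mitigates-internalization
ordering D(const) > D(30 min) > D(120 min) with D(120) below a tenth of
D(const) for both PLC and Egr1; PLC spike-then-plateau only with
internalization; near-maximal pulsatile output at the 1× rates; fast
upstream and slow downstream on/off kinetics; and the gate shapes below.
The resting steady state is constructed algebraically (the unstimulated
system is block-triangular), verified to residual < 10⁻¹⁰, checked for
local stability, and used as the initial condition of every simulation.

## Transcription gates

`ERK_DT`, `NFAT_DT`, `AND`, `OR` are instantaneous Hill combinations of
nuclear ppERK (E) and the NFAT nuclear fraction (N). Their half-
saturation constants ship very low (0.002 in channel units, h = 2):
these gates are committed on-switches, so their reporter output tracks
*time in the on state* and rises monotonically with pulse frequency and
with concentration.

`COOP` is kinetic: the promoter binds NFAT first (b₁ = 0.005 /min per
NF unit, u₁ = 0.008 /min — priming integrates N over ~2 h) and the
ERK-dependent factor only from the NFAT-bound state (b₂ = 5 /µM/min,
u₂ = 2 /min — fast), transcribing from the doubly-bound state. Two
consequences follow from the timescales rather than from any fitted
shape: (i) the slow priming step makes the 960-min reporter AUC
insensitive to the stimulation-onset transient (the promoter is not yet
primed when the shared initial Ca²⁺/ppERK burst occurs), and (ii) in
its near-linear operating regime the gate's output tracks the product
N·E, so it rewards *coincidence* of the slow and fast signals. Under
pulsed stimulation both time-averaged calcineurin drive and time-
averaged nuclear ppERK exceed their constant-stimulation values (the
release-gate and Ca²⁺-Hill convexities above), so the co-operative
reporter peaks at an interior pulse frequency at every internalization
rate tested (0.001×, 0.5×, 1×), and at 0.5×/0.001× its dose response
peaks at sub-maximal concentration while all other gates stay monotone
(`scripts/calibrate_gates.py` re-audits all of this). Binding order is
a modeling choice; NFAT-first is the default because NFAT is the slow
signal. Basal transcription is zero and the reporter starts at its
basal fixed point.

## Scans and shape classification

Scans run one simulation per condition from the resting state and
integrate each channel over exactly 960 min (configurable). A response
curve ordered by increasing frequency (or dose) is *bell-shaped* when
an interior point exceeds both endpoints by more than `tol` (default
5 %) relative, *monotonic increasing* when every successive value is at
least the previous times (1 − tol/10); ties in optimum-period search
within 0.1 % break toward the longer period and are flagged. The
period grid {5 (constant), 15, 30, 60, 120, 240, 480} min divides the
960-min horizon evenly.

## Single-cell variability and mutual information

The population generator draws per-cell log-normal factors (unit mean;
default CV 0.3 on receptor and ERK totals — expression-level
differences are the dominant, slowly varying source of cell-to-cell
variability) from per-cell seed substreams spawned from
`(seed, level, cell)`, runs the network (or a configured response
function) under constant stimulation per level, and records a
single-time-point readout plus optional Gaussian measurement noise.
The default eight-level stimulus grid spans 10⁻¹¹–10⁻⁶ M (a 3-bit
input). Snapshot readouts are a deliberate simplification; they
underestimate what a cell could extract from a full trajectory, and
trajectory-based information measures are out of scope.

The MI estimator discretizes responses into quantile bins (default 16,
computed on the pooled sample and then held fixed), tabulates the
level × bin joint distribution, and reports plug-in MI with a
leave-one-out jackknife bias correction (grouped by contingency cell,
so the correction costs one evaluation per occupied cell) clamped to
[0, min(log₂ levels, log₂ bins)], plus a percentile bootstrap CI over
cells resampled within levels. Quantile binning makes the estimate
exactly invariant under common monotone rescaling of all responses —
which is why proportional adaptation (responses and spread shrinking
together) preserves MI while amplitude-only adaptation (means shrink,
absolute spread kept) destroys it. Against an exact quadrature oracle
(Gaussian mixture channel, per-level bin probabilities by CDF
differences over the estimator's own edges) the corrected estimate
agrees to < 0.05 bits at 1000 cells/level. No equivalence with any
published experimental MI value is claimed; the estimator definition is
this package's own.

## What the synthetic data do and do not show

The generator emulates graded, saturating dose-responses with
overlapping single-cell distributions and reproducible heterogeneity.
It does not emulate measurement-specific artifacts (segmentation error,
fluorophore maturation, photobleaching), temporal correlation within a
cell, bimodal/all-or-none responding subpopulations, or extrinsic
correlations between parameters. Tests passing on these populations
demonstrate estimator correctness and the qualitative variability
scenarios, not the information content of any real dataset.

## Numerical choices

Square-wave inputs are discontinuous, so all ODE integration is
segment-wise between pulse edges (LSODA within each smooth segment),
rtol 10⁻⁸ / atol 10⁻¹⁰ by default, dense output on a 0.1-min grid,
trapezoidal AUC. Refinement checks (10× finer grid, rtol 10⁻¹⁰) change
AUCs by well under 0.1 %. Scans in the calibration audit scripts
default to rtol 10⁻⁶ for speed; every shipped ordinal outcome is
identical at both tolerances. The reporter and promoter ODEs are
integrated on the network's output grid with a 2.5-min step cap so
5-min pulses cannot be stepped over. Problem sizes throughout (960-min
horizons, 7-period grids, 11-point multiplier ladders, ≤ 300 cells per
level in tests) are desk-scale by design.

## Known limitations

- The network is a minimal topology: no electrophysiology, no explicit
  IP₃/store dynamics, no secretion, no ERK-mediated feedback, no
  RGS2/phosphatase induction (mechanisms deliberately excluded so that
  receptor trafficking is the only upstream negative feedback).
- Parameters are calibrated to ordinal claims, not fitted to data;
  absolute concentrations and times are plausible but not quantitative
  predictions.
- The Ca²⁺ channel's mild dose non-monotonicity at low internalization
  (the release-gate's falling branch) is the price of the bell-shaped
  co-operative dose responses: a network whose steady states were all
  monotone in dose, driving a monotone gate, could not produce them at
  all, so some intermediate channel must carry the decline.
- Trajectory-based (dynamic) information measures, channel-capacity
  optimization and promoter-specific gene models are out of scope.
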