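"""Bell-shaped frequency responses from co-operative convergence.

Drives the AND gate and the sequential co-operative gate from network
simulations with negligible receptor internalization (0.001x), over
pulse periods from constant stimulation down to 480 min, and prints
the 960-min reporter AUCs.  The AND gate (like the single-factor and
OR gates) peaks at constant stimulation; the co-operative gate peaks
at a sub-maximal pulse frequency even though there is essentially no
upstream negative feedback — coincidence detection between the slow
NFAT signal and the fast ppERK signal produces the bell on its own.
"""
import numpy as np
from gnrhsim import GateSpec, NetworkParams, PulseProtocol, simulate_network, simulate_reporter

params = NetworkParams().with_multipliers(int_mult=0.001)
periods = (5, 15, 30, 60, 120, 240, 480)
aucs = {"AND": [], "COOP": []}
for T in periods:
    proto = (PulseProtocol(1e-7, 5.0, T, 960.0) if T > 5
             else PulseProtocol(1e-7, 960.0, 960.0, 960.0))
    tc = simulate_network(params, proto, rtol=1e-6, atol=1e-9)
    for mode in aucs:
        aucs[mode].append(simulate_reporter(tc, GateSpec(mode=mode))[1])
print(f"{'period min':>10} {'AND AUC':>10} {'COOP AUC':>10}")
for T, a, c in zip(periods, aucs["AND"], aucs["COOP"]):
    label = "constant" if T == 5 else f"{T:.0f}"
    print(f"{label:>10} {a:10.1f} {c:10.2f}")
print("\nThe AND gate saturates toward high frequency; COOP peaks at an "
      "interior period\n(a bell-shaped frequency response without negative "
      "feedback).")
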