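"""Optimal pulse frequency shifts with receptor internalization rate.

Scans pulse periods {15, 30, 60} min (5-min pulses, 1e-7 M GnRH,
960-min Ca2+ AUC) at internalization multipliers 1x, 8x and 16x of the
base rate.  The period giving the largest Ca2+ output lengthens as
internalization strengthens: stronger upstream negative feedback
favors sparser pulses.
"""
import numpy as np
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
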