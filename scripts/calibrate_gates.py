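#!/usr/bin/env python
"""Re-check the calibration of the shipped transcription-gate defaults.

Verifies the frequency- and dose-response shape claims for all five
gate modes at internalization multipliers 0.001x, 0.5x and 1x:
single-factor, AND and OR gates are monotonically increasing on both
axes; the co-operative gate is bell-shaped in pulse frequency at all
three multipliers and bell-shaped in concentration at 0.5x and 0.001x
(monotonic at 1x).  Prints PASS/FAIL per item.

Usage:  python scripts/calibrate_gates.py  [--rtol 1e-6]
"""

from __future__ import annotations

import argparse

import numpy as np

from gnrhsim.gates import GateSpec, simulate_reporter
from gnrhsim.network import NetworkParams, simulate_network
from gnrhsim.pulses import PulseProtocol
from gnrhsim.scan import DEFAULT_PERIOD_GRID, classify_shape

INT_MULTS = (0.001, 0.5, 1.0)
DOSES = (1e-11, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)
MODES = ("ERK_DT", "NFAT_DT", "AND", "OR", "COOP")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--rtol", type=float, default=1e-6)
    args = parser.parse_args()
    rtol, atol = args.rtol, args.rtol * 1e-3
    params = NetworkParams()
    all_ok = True

    print("simulating network conditions ...")
    freq_tc, dose_tc = {}, {}
    for mult in INT_MULTS:
        p = params.with_multipliers(int_mult=mult)
        for period in DEFAULT_PERIOD_GRID:
            proto = (PulseProtocol(1e-7, 5.0, period, 960.0) if period > 5
                     else PulseProtocol(1e-7, 960.0, 960.0, 960.0))
            freq_tc[(mult, period)] = simulate_network(p, proto,
                                                       rtol=rtol, atol=atol)
        for conc in DOSES:
            dose_tc[(mult, conc)] = simulate_network(
                p, PulseProtocol(conc, 960.0, 960.0, 960.0),
                rtol=rtol, atol=atol)

    def check(name, ok, detail=""):
        nonlocal all_ok
        all_ok &= ok
        print(f"[{'PASS' if ok else 'FAIL'}] {name}"
              + (f"  ({detail})" if detail else ""))

    for mode in MODES:
        gate = GateSpec(mode=mode)
        for mult in INT_MULTS:
            freq = np.array([
                simulate_reporter(freq_tc[(mult, T)], gate)[1]
                for T in DEFAULT_PERIOD_GRID])[::-1]
            dose = np.array([
                simulate_reporter(dose_tc[(mult, c)], gate)[1]
                for c in DOSES])
            fshape, dshape = classify_shape(freq), classify_shape(dose)
            if mode == "COOP":
                check(f"COOP frequency bell at {mult}x",
                      fshape == "bell_shaped",
                      f"interior/const = {max(freq[1:-1]) / freq[-1]:.3f}")
                if mult in (0.001, 0.5):
                    check(f"COOP dose bell at {mult}x",
                          dshape == "bell_shaped",
                          f"interior/top = {max(dose[1:-1]) / dose[-1]:.3f}")
                else:
                    check("COOP dose monotonic at 1x",
                          dshape == "monotonic_increasing")
            else:
                check(f"{mode} frequency monotonic at {mult}x",
                      fshape == "monotonic_increasing")
                check(f"{mode} dose monotonic at {mult}x",
                      dshape == "monotonic_increasing")

    print("\nall constraints satisfied" if all_ok
          else "\nSOME CONSTRAINTS FAILED")
    raise SystemExit(0 if all_ok else 1)


if __name__ == "__main__":
    main()
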