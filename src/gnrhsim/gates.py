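"""Transcriptional logic gates downstream of nuclear ppERK and NFAT.

Gonadotropin-gene promoters integrate at least two GnRH-driven inputs:
a fast, ERK-dependent transcription factor (read out here as nuclear
ppERK) and the slow, Ca2+/calcineurin-driven NFAT (read out as its
nuclear fraction).  Five gate modes map the two signals onto a
transcription rate:

``ERK_DT`` / ``NFAT_DT``
    single-factor drive, vmax * Hill(TF);
``AND`` / ``OR``
    instantaneous Boolean-like combinations of the two Hills;
``COOP``
    sequential co-operative binding: NFAT occupies the promoter first
    (slow on/off, matching its translocation timescale), and the
    ERK-dependent factor binds productively only to the NFAT-primed
    promoter (fast on/off).  Transcription proceeds from the
    doubly-bound state.

The COOP mode is the interesting one: because the priming step
integrates the slow NFAT signal while the second step samples the
fast ppERK signal, the gate responds to the *coincidence* of the two,
and its frequency response is bell-shaped — maximal reporter output at
sub-maximal pulse frequency — even when receptor internalization (the
only upstream negative feedback) is negligible.  The single-factor,
AND and OR gates are monotonic in pulse frequency under the same
conditions.  Gate parameters ship calibrated to those shape claims;
``scripts/calibrate_gates.py`` re-checks them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.integrate import solve_ivp

from .timecourse import Timecourse

__all__ = [
    "GateMode",
    "GateSpec",
    "ReporterState",
    "gate_rate",
    "coop_stationary_occupancy",
    "simulate_reporter",
]


class GateMode(str, Enum):
    ERK_DT = "ERK_DT"
    NFAT_DT = "NFAT_DT"
    AND = "AND"
    OR = "OR"
    COOP = "COOP"


@dataclass(frozen=True)
class GateSpec:
    """Gate mode plus kinetic constants.

    ``K_E``/``K_N`` are half-saturation constants in the units of the
    driving channels (µM nuclear ppERK; NFAT nuclear fraction).  The
    single-factor, AND and OR gates are deliberately easy to saturate
    (small K): they represent committed "on" switches.  The COOP gate's
    binding steps are kinetic: NFAT binds first (``b1``/``u1``, slow),
    the ERK-dependent factor second (``b2``/``u2``, fast).
    """

    mode: GateMode | str = GateMode.COOP
    K_E: float = 0.002     # µM, single-factor/AND/OR half-max for ppERK
    K_N: float = 0.002     # nuclear fraction half-max for NFAT
    h_E: float = 2.0
    h_N: float = 2.0
    b1: float = 0.005       # /min per NF unit, NFAT binding (priming, slow)
    u1: float = 0.008      # /min NFAT unbinding
    b2: float = 5.0        # /min per µM ppERK, second-factor binding (fast)
    u2: float = 2.0        # /min second-factor unbinding
    vmax: float = 0.2      # µM/min maximal transcription rate
    kdeg: float = 0.05     # /min reporter turnover

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", GateMode(self.mode))
        for name in ("K_E", "K_N", "b1", "u1", "b2", "u2", "vmax", "kdeg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("h_E", "h_N"):
            if not (1.0 <= getattr(self, name) <= 4.0):
                raise ValueError(f"{name} must lie in [1, 4]")


@dataclass
class ReporterState:
    """Promoter occupancies (COOP only) and reporter abundance."""

    p_empty: float = 1.0
    p_nfat: float = 0.0      # NFAT-bound (primed)
    p_double: float = 0.0    # NFAT + ERK-factor bound (transcribing)
    reporter: float = 0.0    # µM

    def occupancies(self) -> np.ndarray:
        return np.array([self.p_empty, self.p_nfat, self.p_double])

    def validate(self) -> None:
        occ = self.occupancies()
        if np.any(occ < -1e-9) or abs(occ.sum() - 1.0) > 1e-6:
            raise ValueError(f"promoter occupancies invalid: {occ}")
        if self.reporter < 0:
            raise ValueError("reporter must be non-negative")


def _hill(x: float | np.ndarray, K: float, h: float):
    xh = np.maximum(x, 0.0) ** h
    return xh / (K ** h + xh)


def gate_rate(E, N, gate: GateSpec,
              promoter: ReporterState | None = None):
    """Transcription rate (µM/min) for signal levels ``E`` and ``N``.

    For the COOP gate the rate reads the doubly-bound occupancy from
    ``promoter`` (the promoter carries the memory of the slow priming
    step); for the instantaneous modes it is a pure function of (E, N).
    """
    mode = GateMode(gate.mode)
    if mode is GateMode.ERK_DT:
        return gate.vmax * _hill(E, gate.K_E, gate.h_E)
    if mode is GateMode.NFAT_DT:
        return gate.vmax * _hill(N, gate.K_N, gate.h_N)
    if mode is GateMode.AND:
        return gate.vmax * _hill(E, gate.K_E, gate.h_E) * _hill(N, gate.K_N, gate.h_N)
    if mode is GateMode.OR:
        he, hn = _hill(E, gate.K_E, gate.h_E), _hill(N, gate.K_N, gate.h_N)
        return gate.vmax * (he + hn - he * hn)
    if mode is GateMode.COOP:
        if promoter is None:
            raise ValueError("COOP gate needs the promoter state")
        return gate.vmax * promoter.p_double
    raise ValueError(f"unknown gate mode {gate.mode!r}")  # pragma: no cover


def coop_stationary_occupancy(E: float, N: float, gate: GateSpec) -> np.ndarray:
    """Closed-form stationary promoter distribution at constant (E, N).

    The chain empty <-> NFAT-bound <-> doubly-bound is a birth-death
    process; detailed balance gives p1/p0 = b1 N/u1 and p2/p1 = b2 E/u2.
    """
    a = gate.b1 * N / gate.u1
    b = gate.b2 * E / gate.u2
    z = 1.0 + a + a * b
    return np.array([1.0, a, a * b]) / z


def simulate_reporter(
    tc: Timecourse,
    gate: GateSpec,
    horizon: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> tuple[Timecourse, float]:
    """Drive the reporter from a network time course.

    Integrates the promoter cycle (COOP) and
    d(reporter)/dt = gate_rate - kdeg * reporter from zero reporter and
    empty promoter, on the time grid of ``tc``.  Returns the reporter
    time course (channels ``reporter`` and, for COOP, the occupancies)
    and the reporter AUC over ``[0, horizon]`` (default 960 min).

    Raises ``KeyError`` if the time course lacks the ``ppERK_nuc`` or
    ``NFAT_NF`` channels.
    """
    horizon = 960.0 if horizon is None else horizon
    t = tc.time
    E_tr, N_tr = tc["ppERK_nuc"], tc["NFAT_NF"]

    def interp(trace):
        def f(tt):
            return float(np.interp(tt, t, trace))
        return f

    E_of, N_of = interp(E_tr), interp(N_tr)
    mode = GateMode(gate.mode)

    if mode is GateMode.COOP:
        def rhs(tt, y):
            p1, p2, rep = y
            p0 = 1.0 - p1 - p2
            E, N = E_of(tt), N_of(tt)
            dp1 = gate.b1 * N * p0 - gate.u1 * p1 - gate.b2 * E * p1 + gate.u2 * p2
            dp2 = gate.b2 * E * p1 - gate.u2 * p2
            drep = gate.vmax * p2 - gate.kdeg * rep
            return [dp1, dp2, drep]
        y0 = [0.0, 0.0, 0.0]
    else:
        def rhs(tt, y):
            rep = y[0]
            rate = gate_rate(E_of(tt), N_of(tt), gate)
            return [rate - gate.kdeg * rep]
        y0 = [0.0]

    sol = solve_ivp(rhs, (t[0], t[-1]), y0, method="LSODA", t_eval=t,
                    rtol=rtol, atol=atol, max_step=2.5)
    if not sol.success:  # pragma: no cover - solver failure path
        raise RuntimeError(f"reporter integration failed: {sol.message}")

    if mode is GateMode.COOP:
        p1, p2, rep = sol.y
        channels = {
            "reporter": rep,
            "promoter_empty": 1.0 - p1 - p2,
            "promoter_nfat": p1,
            "promoter_double": p2,
        }
    else:
        rep = sol.y[0]
        channels = {"reporter": rep}
    out = Timecourse(time=t, channels=channels,
                     meta={**tc.meta, "gate": gate})
    return out, out.auc("reporter", horizon)
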