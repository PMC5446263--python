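"""Frequency-response and dose-response scanning with AUC readouts.

The system output throughout is the area under a channel's time course
over a fixed horizon (960 min by default), computed on the raw,
non-baseline-subtracted trace.  Scans return a tidy :class:`ScanResult`
from which the optimum stimulation condition and the qualitative shape
of the response curve (monotonic versus bell-shaped, i.e. maximal
output at sub-maximal pulse frequency) can be read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._ode import DEFAULT_ATOL, DEFAULT_RTOL
from .network import NetworkParams, simulate_network
from .pulses import PulseProtocol
from .timecourse import Timecourse

__all__ = [
    "ScanResult",
    "frequency_scan",
    "dose_scan",
    "optimal_period",
    "classify_shape",
    "DEFAULT_PERIOD_GRID",
    "NETWORK_CHANNELS",
]

#: Pulse-period grid (min) used for network frequency scans; the first
#: entry equals the pulse width, i.e. constant stimulation.
DEFAULT_PERIOD_GRID = (5.0, 15.0, 30.0, 60.0, 120.0, 240.0, 480.0)

NETWORK_CHANNELS = ("HR", "PLC", "Ca", "ppERK_nuc", "NFAT_NF", "Egr1")

OPTIMUM_TIE_TOL = 1e-3  # 0.1 % relative


@dataclass
class ScanResult:
    """AUCs per channel along one scan axis.

    ``axis_name`` is ``"period_min"`` for frequency scans (ordered by
    increasing period) or ``"concentration_M"`` for dose scans.
    """

    axis_name: str
    axis: np.ndarray
    aucs: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("scan axis must be strictly increasing")
        for name, col in self.aucs.items():
            col = np.asarray(col, dtype=float)
            if len(col) != len(self.axis):
                raise ValueError(f"channel {name!r} length mismatch")
            if np.any(col < -1e-12):
                raise ValueError(f"channel {name!r} has negative AUC")
            self.aucs[name] = col

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.aucs[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available: {sorted(self.aucs)}"
            ) from None

    def by_increasing_frequency(self, name: str) -> np.ndarray:
        """Channel AUCs ordered from lowest to highest pulse frequency."""
        if self.axis_name != "period_min":
            raise ValueError("frequency ordering only applies to period scans")
        return self.channel(name)[::-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per condition per channel."""
        rows = []
        for i, x in enumerate(self.axis):
            for name, col in self.aucs.items():
                row = {self.axis_name: x, "channel": name, "auc": col[i]}
                row.update(self.meta)
                rows.append(row)
        return pd.DataFrame(rows)


def _channel_aucs(tc: Timecourse, horizon: float,
                  channels: Sequence[str]) -> dict[str, float]:
    return {name: tc.auc(name, horizon) for name in channels}


def frequency_scan(
    params: NetworkParams | None = None,
    periods: Sequence[float] = DEFAULT_PERIOD_GRID,
    width: float = 5.0,
    amplitude: float = 1e-7,
    horizon: float = 960.0,
    channels: Sequence[str] = NETWORK_CHANNELS,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ScanResult:
    """One network simulation per pulse period, from the resting state.

    Constant stimulation is encoded as ``period == width``.  Every
    simulation starts from the resting steady state; AUCs are over
    ``[0, horizon]`` on the raw traces.
    """
    params = NetworkParams() if params is None else params
    periods = sorted(float(T) for T in periods)
    if any(T < width for T in periods):
        raise ValueError("every period must be >= the pulse width")
    aucs: dict[str, list[float]] = {name: [] for name in channels}
    failures: list[str] = []
    for T in periods:
        proto = PulseProtocol(amplitude=amplitude, width=width, period=T,
                              horizon=horizon)
        try:
            tc = simulate_network(params, proto, rtol=rtol, atol=atol)
        except Exception as exc:  # pragma: no cover - solver failure path
            raise RuntimeError(
                f"frequency scan failed at period {T} min "
                f"(int_mult={params.int_mult}): {exc}"
            ) from exc
        for name, value in _channel_aucs(tc, horizon, channels).items():
            aucs[name].append(value)
    return ScanResult(
        axis_name="period_min",
        axis=np.array(periods),
        aucs={k: np.array(v) for k, v in aucs.items()},
        meta={
            "width_min": width,
            "amplitude_M": amplitude,
            "horizon_min": horizon,
            "int_mult": params.int_mult,
            "rec_mult": params.rec_mult,
            "ca_auc_baseline_subtracted": False,
        },
    )


def dose_scan(
    params: NetworkParams | None = None,
    concentrations: Sequence[float] = (1e-11, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6),
    horizon: float = 960.0,
    channels: Sequence[str] = NETWORK_CHANNELS,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ScanResult:
    """Constant stimulation at each GnRH concentration; AUC per channel."""
    params = NetworkParams() if params is None else params
    concentrations = sorted(float(c) for c in concentrations)
    aucs: dict[str, list[float]] = {name: [] for name in channels}
    for conc in concentrations:
        proto = PulseProtocol(amplitude=conc, width=horizon,
                              period=horizon, horizon=horizon)
        tc = simulate_network(params, proto, rtol=rtol, atol=atol)
        for name, value in _channel_aucs(tc, horizon, channels).items():
            aucs[name].append(value)
    return ScanResult(
        axis_name="concentration_M",
        axis=np.array(concentrations),
        aucs={k: np.array(v) for k, v in aucs.items()},
        meta={
            "horizon_min": horizon,
            "int_mult": params.int_mult,
            "rec_mult": params.rec_mult,
            "constant_stimulation": True,
        },
    )


def optimal_period(scan: ScanResult, channel: str) -> tuple[float, bool]:
    """Period (min) maximizing the channel AUC.

    Ties within 0.1 % relative are broken toward the *longer* period and
    flagged: returns ``(period, tie_declared)``.
    """
    if scan.axis_name != "period_min":
        raise ValueError("optimal_period requires a period scan")
    if len(scan.axis) < 2:
        raise ValueError("need at least two periods")
    col = scan.channel(channel)
    best = float(np.max(col))
    near = scan.axis[col >= best * (1.0 - OPTIMUM_TIE_TOL)]
    return float(near[-1]), bool(len(near) > 1)


def classify_shape(values: "ScanResult | Sequence[float]",
                   channel: str | None = None,
                   tol: float = 0.05) -> str:
    """Classify a response curve ordered by increasing frequency (or dose).

    Returns ``"bell_shaped"`` when an interior point exceeds *both*
    endpoints by more than ``tol`` relative (maximal output at a
    sub-maximal frequency), ``"monotonic_increasing"`` when every
    successive value is at least ``previous * (1 - tol/10)``, and
    ``"other"`` otherwise.

    Accepts either a :class:`ScanResult` plus channel name (period
    scans are re-ordered to increasing frequency automatically) or a
    bare sequence already ordered along the axis of interest.
    """
    if isinstance(values, ScanResult):
        if channel is None:
            raise ValueError("channel is required with a ScanResult")
        if values.axis_name == "period_min":
            seq = values.by_increasing_frequency(channel)
        else:
            seq = values.channel(channel)
    else:
        seq = np.asarray(values, dtype=float)
    if len(seq) < 3:
        raise ValueError("need at least three points to classify a shape")
    interior_max = float(np.max(seq[1:-1]))
    if interior_max > (1.0 + tol) * seq[0] and interior_max > (1.0 + tol) * seq[-1]:
        return "bell_shaped"
    if np.all(seq[1:] >= seq[:-1] * (1.0 - tol / 10.0)):
        return "monotonic_increasing"
    return "other"
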