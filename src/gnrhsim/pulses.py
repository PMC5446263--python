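"""Square-wave pulsatile stimulus protocols.

GnRH reaches the gonadotrope as a train of short secretory pulses.  All
simulations in this package drive their models with an idealized square
wave: concentration ``amplitude`` for ``width`` minutes at the start of
every ``period``, and ``baseline`` (normally zero) in between, over a
total ``horizon``.  ``width == period`` encodes constant stimulation.

Two protocol families recur throughout the analyses:

* *non-compensated*: pulse width fixed, period varied, so the input
  integral (stimulus AUC) grows in direct proportion to pulse frequency;
* *compensated*: one duty fraction shared by all members, so every
  protocol delivers exactly the same input integral regardless of
  frequency (more, briefer pulses versus fewer, longer ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PulseProtocol",
    "signal_at",
    "input_integral",
    "compensated_family",
]


@dataclass(frozen=True)
class PulseProtocol:
    """A square-wave stimulus train.

    Parameters
    ----------
    amplitude : float
        Stimulus concentration during a pulse (M).
    width : float
        Pulse duration (min).
    period : float
        Pulse interval, start to start (min).  ``width == period`` is
        constant stimulation.
    horizon : float
        Total simulated time (min).
    baseline : float
        Concentration between pulses (M), default 0.
    """

    amplitude: float
    width: float
    period: float
    horizon: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.width <= self.period):
            raise ValueError(
                f"require 0 < width <= period, got width={self.width}, "
                f"period={self.period}"
            )
        if self.horizon <= 0:
            raise ValueError(f"horizon must be positive, got {self.horizon}")
        if not (self.amplitude >= self.baseline >= 0):
            raise ValueError(
                "require amplitude >= baseline >= 0, got "
                f"amplitude={self.amplitude}, baseline={self.baseline}"
            )

    @property
    def is_constant(self) -> bool:
        """True when the protocol is constant stimulation."""
        return self.width == self.period

    @property
    def frequency_per_hr(self) -> float:
        """Pulse frequency in pulses per hour."""
        return 60.0 / self.period

    def edges(self, t_end: float | None = None) -> np.ndarray:
        """Sorted pulse on/off switch times in (0, t_end).

        Used by the integrators to split the time axis into segments on
        which the stimulus is constant.
        """
        t_end = self.horizon if t_end is None else t_end
        if self.is_constant:
            return np.empty(0)
        out = []
        n = 0
        while n * self.period < t_end:
            start = n * self.period
            if 0 < start < t_end:
                out.append(start)
            off = start + self.width
            if 0 < off < t_end:
                out.append(off)
            n += 1
        return np.array(sorted(out))


def signal_at(protocol: PulseProtocol, t) -> float | np.ndarray:
    """Stimulus concentration (M) at time ``t`` (min).

    Pulses start at t = 0; the value is ``amplitude`` while
    ``t mod period < width`` and ``baseline`` otherwise.  Accepts a
    scalar or an array; ``t`` must lie within [0, horizon].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > protocol.horizon):
        raise ValueError(
            f"t must lie in [0, {protocol.horizon}] min, got {t!r}"
        )
    if protocol.is_constant:
        value = np.full_like(t_arr, protocol.amplitude)
    else:
        phase = np.mod(t_arr, protocol.period)
        value = np.where(phase < protocol.width, protocol.amplitude,
                         protocol.baseline)
    return float(value) if np.isscalar(t) or t_arr.ndim == 0 else value


def input_integral(protocol: PulseProtocol, horizon: float | None = None) -> float:
    """Exact integral of the stimulus over [0, horizon] (M*min).

    Counts partial trailing pulses.  ``horizon`` defaults to the
    protocol's own horizon and may not exceed it.
    """
    horizon = protocol.horizon if horizon is None else horizon
    if horizon > protocol.horizon:
        raise ValueError(
            f"horizon {horizon} exceeds protocol horizon {protocol.horizon}"
        )
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    n_full = math.floor(horizon / protocol.period)
    rem = horizon - n_full * protocol.period
    on_time = n_full * protocol.width + min(rem, protocol.width)
    off_time = horizon - on_time
    return protocol.amplitude * on_time + protocol.baseline * off_time


def compensated_family(
    duty_fraction: float,
    periods: list[float],
    amplitude: float,
    horizon: float,
    baseline: float = 0.0,
) -> list[PulseProtocol]:
    """Protocols with equal input integral at every frequency.

    Each member gets ``width = duty_fraction * period`` so that over a
    horizon that is a common multiple of all periods the stimulus AUC is
    identical (to machine precision) across the family.

    Raises
    ------
    ValueError
        If ``duty_fraction`` is outside (0, 1] or ``horizon`` is not a
        common multiple of every period (partial trailing pulses would
        break the equal-integral guarantee).
    """
    if not (0 < duty_fraction <= 1):
        raise ValueError(f"duty_fraction must be in (0, 1], got {duty_fraction}")
    for period in periods:
        cycles = horizon / period
        if abs(cycles - round(cycles)) > 1e-9 * max(1.0, cycles):
            raise ValueError(
                f"horizon {horizon} is not a multiple of period {period}; "
                "input integrals would differ across the family"
            )
    return [
        PulseProtocol(
            amplitude=amplitude,
            width=duty_fraction * period,
            period=period,
            horizon=horizon,
            baseline=baseline,
        )
        for period in periods
    ]
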