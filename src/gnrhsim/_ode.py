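"""Segment-wise stiff integration of pulse-driven ODE systems.

A square-wave stimulus is discontinuous at every pulse edge, which
defeats adaptive step control if the integrator is allowed to step
across an edge.  All simulators in this package therefore integrate
segment by segment: within a segment the stimulus is constant, so the
right-hand side is smooth and LSODA can take long steps.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failure context."""

    def __init__(self, message: str, t_fail: float, context: dict | None = None):
        super().__init__(message)
        self.t_fail = t_fail
        self.context = context or {}


def integrate_pulsed(
    rhs: Callable[[float, np.ndarray, float], np.ndarray],
    y0: Sequence[float],
    edges: np.ndarray,
    stimulus_after: Callable[[float], float],
    t_grid: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    context: dict | None = None,
) -> np.ndarray:
    """Integrate ``dy/dt = rhs(t, y, S)`` over a piecewise-constant stimulus.

    Parameters
    ----------
    rhs : callable
        ``rhs(t, y, stimulus_value) -> dy/dt``.
    y0 : array-like
        Initial state at ``t_grid[0]``.
    edges : ndarray
        Sorted stimulus switch times strictly inside the grid span.
    stimulus_after : callable
        ``stimulus_after(t) -> S`` evaluated just after time ``t``; must be
        constant between consecutive edges.
    t_grid : ndarray
        Uniform output grid (must start at the initial time).

    Returns
    -------
    ndarray of shape (len(t_grid), len(y0)) with the trajectory.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    breaks = np.concatenate(([t0], edges[(edges > t0) & (edges < t_end)], [t_end]))

    out = np.empty((len(t_grid), len(y0)))
    out[0] = y0
    y = np.asarray(y0, dtype=float)
    eps = 1e-9
    for a, b in zip(breaks[:-1], breaks[1:]):
        stim = stimulus_after(a + min(eps, (b - a) / 2))
        # grid points strictly inside (a, b], segment end handled via b
        mask = (t_grid > a + 1e-12) & (t_grid <= b + 1e-12)
        t_eval = t_grid[mask]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval if len(t_eval) else None,
            rtol=rtol,
            atol=atol,
            args=(stim,),
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed at t={sol.t[-1] if len(sol.t) else a:.3f} "
                f"min: {sol.message}",
                t_fail=float(sol.t[-1]) if len(sol.t) else a,
                context=context,
            )
        if len(t_eval):
            out[mask] = sol.y.T
            y = sol.y[:, -1]
            if abs(t_eval[-1] - b) > 1e-9:
                # advance the carried state to the exact segment end
                sol2 = solve_ivp(rhs, (t_eval[-1], b), y, method="LSODA",
                                 rtol=rtol, atol=atol, args=(stim,))
                if not sol2.success:
                    raise IntegrationError(
                        f"ODE integration failed at t={b:.3f} min: {sol2.message}",
                        t_fail=b, context=context)
                y = sol2.y[:, -1]
        else:
            y = sol.y[:, -1]
    return out


def trapezoid_auc(t: np.ndarray, y: np.ndarray, horizon: float) -> float:
    """Trapezoidal AUC of a sampled trace over [t[0], horizon]."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if horizon > t[-1] + 1e-9:
        raise ValueError(
            f"horizon {horizon} exceeds sampled trace end {t[-1]}"
        )
    mask = t <= horizon + 1e-9
    return float(np.trapezoid(y[mask], t[mask]))
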