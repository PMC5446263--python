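"""Uniform-grid time courses shared by every simulator in the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ode import trapezoid_auc

__all__ = ["Timecourse"]


@dataclass
class Timecourse:
    """A set of named channels sampled on one uniform time grid.

    ``time`` is in minutes; channel units are whatever the producing
    model reports (a.u. for the minimal cascade, µM or fractions for the
    receptor network).  ``meta`` carries provenance (model, protocol,
    solver tolerances) written into CSV headers on export.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name, trace in self.channels.items():
            if len(trace) != n:
                raise ValueError(
                    f"channel {name!r} has {len(trace)} samples, expected {n}"
                )

    def __getitem__(self, channel: str) -> np.ndarray:
        try:
            return self.channels[channel]
        except KeyError:
            raise KeyError(
                f"unknown channel {channel!r}; available: "
                f"{sorted(self.channels)}"
            ) from None

    def auc(self, channel: str, horizon: float | None = None) -> float:
        """Trapezoidal AUC of one channel over [0, horizon]."""
        horizon = float(self.time[-1]) if horizon is None else horizon
        return trapezoid_auc(self.time, self[channel], horizon)

    def to_frame(self) -> pd.DataFrame:
        """Tidy wide table: one time column plus one column per channel."""
        data = {"time_min": self.time}
        data.update(self.channels)
        return pd.DataFrame(data)
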