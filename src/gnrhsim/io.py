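"""Tabular output with provenance headers.

All results leave the package as CSV: a commented header block carries
the provenance (config hash, seed, solver tolerances), followed by a
plain table at >= 12 significant digits, so identical configurations
produce byte-identical data sections.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .scan import ScanResult
from .timecourse import Timecourse

__all__ = ["write_timecourse", "write_scan", "write_table", "read_table"]

_FLOAT_FMT = "%.12g"

# CSV column names for the network channels (units in the name)
NETWORK_CSV_COLUMNS = {
    "HR": "HR_uM",
    "PLC": "PLC_uM",
    "Ca": "Ca_uM",
    "ppERK_nuc": "ppERK_nuc_uM",
    "NFAT_NF": "NFAT_NF",
    "Egr1": "Egr1_uM",
}


def _header_lines(meta: dict) -> list[str]:
    lines = ["# gnrhsim output"]
    for key in sorted(meta):
        value = meta[key]
        if hasattr(value, "amplitude"):  # PulseProtocol
            value = (f"amplitude_M={value.amplitude:g} width_min={value.width:g} "
                     f"period_min={value.period:g} horizon_min={value.horizon:g}")
        lines.append(f"# {key}: {value}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write a DataFrame as CSV with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(meta or {}):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


def write_timecourse(tc: Timecourse, path: str | Path,
                     channels: list[str] | None = None,
                     extra_meta: dict | None = None) -> Path:
    """Write a time course; network channels get their unit-bearing names."""
    df = tc.to_frame()
    if channels is not None:
        df = df[["time_min"] + channels]
    df = df.rename(columns=NETWORK_CSV_COLUMNS)
    meta = dict(tc.meta)
    meta.update(extra_meta or {})
    return write_table(df, path, meta)


def write_scan(scan: ScanResult, path: str | Path,
               extra_meta: dict | None = None) -> Path:
    """Write a scan result as a tidy table (one row per condition/channel)."""
    df = scan.to_frame()
    meta = dict(scan.meta)
    meta.update(extra_meta or {})
    return write_table(df, path, meta)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by this module (comment lines skipped)."""
    return pd.read_csv(path, comment="#")
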