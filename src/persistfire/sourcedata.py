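"""Optional reader for per-figure source-data tables.

Published source-data spreadsheets ship in heterogeneous layouts, so this
reader consumes a *tidy* normalization of them (CSV or XLSX) that the user
prepares once:

* firing-rate data: columns ``group, cell, kind, index, value`` where
  ``kind`` is ``"bin"`` (index = 0-based 1 s bin, value = rate in spikes/s,
  already averaged over the three sweeps) or ``"sweep_mean"`` (index =
  sweep number, value = that sweep's mean rate);
* per-sweep amplitude data (AHP / ADP): columns
  ``group, cell, sweep, value``.

These feed the acceptance recomputations when the files are present; the
rest of the pipeline never depends on them.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def load_rate_curves(path, group: str) -> np.ndarray:
    """Per-cell binned rate curves for one group: cells x bins array."""
    df = _read_table(path)
    df = df[(df["group"] == group) & (df["kind"] == "bin")]
    if not len(df):
        raise ValueError(f"no bin rows for group {group!r} in {path}")
    curves = df.pivot_table(index="cell", columns="index", values="value")
    curves = curves.sort_index(axis=1)
    return curves.to_numpy(dtype=float)


def load_sweep_mean_rates(path, group: str) -> np.ndarray:
    """Per-cell arrays of per-sweep mean rates for one group."""
    df = _read_table(path)
    df = df[(df["group"] == group) & (df["kind"] == "sweep_mean")]
    if not len(df):
        raise ValueError(f"no sweep_mean rows for group {group!r} in {path}")
    piv = df.pivot_table(index="cell", columns="index", values="value")
    return piv.to_numpy(dtype=float)


def load_sweep_values(path, group: str) -> np.ndarray:
    """Per-cell per-sweep amplitudes (AHP or ADP tables): cells x sweeps."""
    df = _read_table(path)
    df = df[df["group"] == group]
    if not len(df):
        raise ValueError(f"no rows for group {group!r} in {path}")
    piv = df.pivot_table(index="cell", columns="sweep", values="value")
    return piv.to_numpy(dtype=float)


def group_mean_of_cell_means(per_cell_per_sweep: np.ndarray) -> float:
    """Average sweeps within cell, then cells within group."""
    return float(np.nanmean(np.nanmean(per_cell_per_sweep, axis=1)))
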