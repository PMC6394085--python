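"""Site counts surviving sweeps over per-call quantities.

How many sites each caller retains as a minimum tumor VAF, alt-read or total
depth cutoff rises is a sensitive fingerprint of caller behaviour: permissive
callers dominate at low VAF. Counts are cumulative (value >= cutoff, ties
kept); a per-bin histogram is also available since a plot axis can be read
either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import MutationCatalog

VARIABLES = ("tumor_vaf", "tumor_alt_depth", "tumor_total_depth")
GROUPINGS = ("all-by-tool", "per-tool-by-subject", "per-subject-by-tool")


@dataclass
class ThresholdSweep:
    variable: str
    grid: np.ndarray
    grouping: str
    counts: dict[Hashable, np.ndarray]  # group key -> counts aligned to grid
    n_missing: dict[Hashable, int]  # sites excluded for a missing value

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.counts, key=str):
            group = key if isinstance(key, str) else "/".join(key)
            for cutoff, n in zip(self.grid, self.counts[key]):
                rows.append({"group": group, "cutoff": cutoff, "n_sites": int(n)})
        return pd.DataFrame(rows, columns=["group", "cutoff", "n_sites"])

    def histogram_frame(self) -> pd.DataFrame:
        """Per-bin counts: sites with grid[i] <= value < grid[i+1]."""
        rows = []
        for key in sorted(self.counts, key=str):
            group = key if isinstance(key, str) else "/".join(key)
            c = self.counts[key]
            binned = np.append(c[:-1] - c[1:], c[-1])
            for cutoff, n in zip(self.grid, binned):
                rows.append({"group": group, "bin_start": cutoff, "n_sites": int(n)})
        return pd.DataFrame(rows, columns=["group", "bin_start", "n_sites"])


def default_grid(variable: str) -> np.ndarray:
    """Default cutoff grids: VAF 0-0.5 step 0.01; depths 0-50 step 1."""
    if variable == "tumor_vaf":
        return np.round(np.arange(0, 0.5 + 1e-9, 0.01), 2)
    if variable in ("tumor_alt_depth", "tumor_total_depth"):
        return np.arange(0, 51, dtype=float)
    raise ValueError(f"unknown sweep variable {variable!r}")


def _group_key(call, grouping: str) -> Hashable:
    if grouping == "all-by-tool":
        return call.caller_id
    if grouping == "per-tool-by-subject":
        return (call.caller_id, call.subject_id)
    if grouping == "per-subject-by-tool":
        return (call.subject_id, call.caller_id)
    raise ValueError(f"unknown grouping {grouping!r}")


def sweep(catalog: MutationCatalog, variable: str,
          grid: Optional[Sequence[float]] = None,
          grouping: str = "all-by-tool") -> ThresholdSweep:
    """Count, per group and cutoff, the sites with ``variable >= cutoff``.

    Calls with a missing value (e.g. VAF at zero depth) are excluded from
    every count and tallied separately per group.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown sweep variable {variable!r}")
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    grid_arr = default_grid(variable) if grid is None else np.asarray(grid, dtype=float)
    if grid_arr.size == 0:
        raise ValueError("empty cutoff grid")
    if np.any(np.diff(grid_arr) <= 0):
        raise ValueError("grid must be strictly increasing")

    values: dict[Hashable, list[float]] = {}
    missing: dict[Hashable, int] = {}
    for call in catalog.iter_calls():
        key = _group_key(call, grouping)
        v = getattr(call, variable)
        if v is None:
            missing[key] = missing.get(key, 0) + 1
            values.setdefault(key, [])
            continue
        values.setdefault(key, []).append(float(v))
        missing.setdefault(key, 0)

    counts: dict[Hashable, np.ndarray] = {}
    for key, vals in values.items():
        arr = np.sort(np.asarray(vals))
        # count of values >= cutoff via right-side search on the sorted array
        counts[key] = arr.size - np.searchsorted(arr, grid_arr, side="left")
    return ThresholdSweep(variable, grid_arr, grouping, counts, missing)
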