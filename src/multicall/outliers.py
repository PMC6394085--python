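"""Outlier subjects under Tukey's fences on four cohort-level criteria.

A subject is flagged when it is (a) hypermutated — total distinct sites above
the high fence; (b) imbalanced in the number of sites across callers — the
coefficient of variation of its per-caller site counts is above the high
fence; (c) imbalanced in consensus among callers — the CV of its pairwise
shared fractions x_ij / min(x_ii, x_jj) is above the high fence; (d) of low
consensus — its consensus score falls below the low fence. The fence
constant k defaults to the classic 1.5 x IQR; quartiles use linear
interpolation between order statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import consensus_per_subject, overlap_tools
from .core import MutationCatalog

log = logging.getLogger(__name__)


@dataclass
class OutlierFlags:
    subject_id: str
    hypermutated: bool
    site_count_imbalance: bool
    consensus_imbalance: bool
    low_cs: bool
    n_sites: int
    imbalance_stat: Optional[float]
    consensus_imbalance_stat: Optional[float]
    cs: Optional[float]


def tukey_fences(values: Sequence[Optional[float]], k: float = 1.5,
                 side: str = "both") -> tuple[np.ndarray, float, float]:
    """Flag values beyond Q1 - k*IQR / Q3 + k*IQR.

    Missing values (None/NaN) are excluded from fence estimation and never
    flagged. Fewer than 4 finite values -> no flags, fences NaN.
    """
    if side not in ("low", "high", "both"):
        raise ValueError(f"invalid side {side!r}")
    arr = np.array([np.nan if v is None else v for v in values], dtype=float)
    finite = arr[np.isfinite(arr)]
    flags = np.zeros(len(arr), dtype=bool)
    if finite.size < 4:
        log.warning("tukey_fences: only %d finite values, no flags", finite.size)
        return flags, float("nan"), float("nan")
    q1, q3 = np.quantile(finite, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    with np.errstate(invalid="ignore"):
        if side in ("low", "both"):
            flags |= arr < lower
        if side in ("high", "both"):
            flags |= arr > upper
    flags &= np.isfinite(arr)
    return flags, float(lower), float(upper)


def _sample_cv(values: np.ndarray) -> Optional[float]:
    """Sample (n-1) coefficient of variation; None for <2 values or mean 0."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return None
    mean = values.mean()
    if mean == 0:
        return None
    return float(values.std(ddof=1) / mean)


def _consensus_imbalance(catalog: MutationCatalog, subject: str) -> Optional[float]:
    """CV of pairwise shared fractions x_ij / min(x_ii, x_jj) within a subject."""
    t = overlap_tools(catalog, scope=subject)
    keep = [i for i in range(len(t.callers)) if t.x[i, i] > 0]
    fractions = [
        t.x[i, j] / min(t.x[i, i], t.x[j, j])
        for i, j in combinations(keep, 2)
    ]
    if len(fractions) < 2:
        return None
    return _sample_cv(np.array(fractions))


def subject_outlier_report(catalog: MutationCatalog, k: float = 1.5
                           ) -> list[OutlierFlags]:
    """Per-subject four-criterion outlier flags across the cohort.

    Requires at least 4 subjects for the fences to be meaningful; subjects
    with an undefined statistic are excluded from that criterion only.
    """
    if len(catalog.subjects) < 4:
        log.warning("outlier report on %d subjects: fences unreliable",
                    len(catalog.subjects))
    records = consensus_per_subject(catalog)
    n_sites = [r.n_sites for r in records]
    imbalance = [
        _sample_cv(np.array([c for c in r.caller_counts.values()]))
        for r in records
    ]
    cons_imb = [_consensus_imbalance(catalog, r.subject_id) for r in records]
    cs = [r.cs for r in records]

    hyper, _, _ = tukey_fences(n_sites, k=k, side="high")
    imb_f, _, _ = tukey_fences(imbalance, k=k, side="high")
    cimb_f, _, _ = tukey_fences(cons_imb, k=k, side="high")
    cs_f, _, _ = tukey_fences(cs, k=k, side="low")

    return [
        OutlierFlags(
            subject_id=r.subject_id,
            hypermutated=bool(hyper[i]),
            site_count_imbalance=bool(imb_f[i]),
            consensus_imbalance=bool(cimb_f[i]),
            low_cs=bool(cs_f[i]),
            n_sites=r.n_sites,
            imbalance_stat=imbalance[i],
            consensus_imbalance_stat=cons_imb[i],
            cs=r.cs,
        )
        for i, r in enumerate(records)
    ]


def outlier_frame(flags: list[OutlierFlags]) -> pd.DataFrame:
    """Report table mirroring the four YES/NO outlier columns."""
    def yn(b: bool) -> str:
        return "YES" if b else "NO"
    return pd.DataFrame([{
        "subject": f.subject_id,
        "n_sites": f.n_sites,
        "imbalance_stat": f.imbalance_stat,
        "consensus_imbalance_stat": f.consensus_imbalance_stat,
        "CS": f.cs,
        "hypermutated": yn(f.hypermutated),
        "site_count_imbalance": yn(f.site_count_imbalance),
        "consensus_imbalance": yn(f.consensus_imbalance),
        "low_CS": yn(f.low_cs),
    } for f in flags])
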