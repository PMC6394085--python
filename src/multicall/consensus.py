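"""Site occurrence across callers and subjects.

The central summary is the consensus score

    CS = [ sum_i ( (1/x_ii) * sum_{j != i} x_ij ) ] / P(n, 2)

where x is the caller-by-caller site co-occurrence matrix (diagonal = total
distinct sites per caller, off-diagonal = shared sites) and
P(n, 2) = n(n-1) is the number of ordered caller pairs. With the
total-sites diagonal, CS is 1 when all callers report identical site sets
and 0 when they are pairwise disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import MutationCatalog

log = logging.getLogger(__name__)


@dataclass
class ToolCooccurrence:
    """Symmetric caller x caller shared-site counts; totals on the diagonal."""

    callers: list[str]
    x: np.ndarray  # (n, n) integer
    scope: str = "cohort"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.x, index=self.callers, columns=self.callers)


@dataclass
class OccurrenceStats:
    """Consensus histogram and exclusivity for one scope."""

    scope: str
    total_sites: int
    caller_counts: dict[str, int]
    histogram: dict[int, int]  # k -> number of sites supported by exactly k callers
    exclusive_fraction: dict[str, Optional[float]]

    @property
    def shared_fraction(self) -> dict[str, Optional[float]]:
        """Per caller, fraction of its sites also found by another caller."""
        return {c: None if f is None else 1.0 - f
                for c, f in self.exclusive_fraction.items()}


@dataclass
class ConsensusRecord:
    subject_id: str
    cs: Optional[float]
    n_sites: int
    caller_counts: dict[str, int]
    frac_k_ge_2: Optional[float]


@dataclass
class SubjectCooccurrence:
    subjects: list[str]
    per_caller: dict[str, np.ndarray]  # caller -> (m, m) shared-site counts
    cv: np.ndarray  # (m, m), NaN where no co-occurrence under any caller


def cooccurrence_from_sets(labels: Sequence[str],
                           sets: Mapping[str, set],
                           scope: str = "cohort") -> ToolCooccurrence:
    """Build the co-occurrence matrix from per-label unit sets."""
    n = len(labels)
    x = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(labels):
        x[i, i] = len(sets[a])
        for j in range(i + 1, n):
            shared = len(sets[a] & sets[labels[j]])
            x[i, j] = x[j, i] = shared
    return ToolCooccurrence(list(labels), x, scope)


def occurrence_stats_from_sets(labels: Sequence[str],
                               sets: Mapping[str, set],
                               scope: str = "cohort") -> OccurrenceStats:
    support: dict[Hashable, int] = {}
    for label in labels:
        for unit in sets[label]:
            support[unit] = support.get(unit, 0) + 1
    histogram: dict[int, int] = {}
    for k in support.values():
        histogram[k] = histogram.get(k, 0) + 1
    exclusive: dict[str, Optional[float]] = {}
    for label in labels:
        total = len(sets[label])
        if total == 0:
            exclusive[label] = None
            continue
        only = sum(1 for unit in sets[label] if support[unit] == 1)
        exclusive[label] = only / total
    return OccurrenceStats(
        scope=scope,
        total_sites=len(support),
        caller_counts={label: len(sets[label]) for label in labels},
        histogram=dict(sorted(histogram.items())),
        exclusive_fraction=exclusive,
    )


def site_statistics(catalog: MutationCatalog,
                    scope: Optional[str] = None) -> OccurrenceStats:
    """Occurrence statistics for the whole cohort or one subject."""
    sets = catalog.site_sets(subject=scope)
    return occurrence_stats_from_sets(
        catalog.callers, sets, scope or "cohort")


def overlap_tools(catalog: MutationCatalog,
                  scope: Optional[str] = None) -> ToolCooccurrence:
    """Caller-by-caller shared-site matrix (cohort or one subject)."""
    sets = catalog.site_sets(subject=scope)
    return cooccurrence_from_sets(catalog.callers, sets, scope or "cohort")


def jaccard_matrix(t: ToolCooccurrence) -> np.ndarray:
    """Pairwise Jaccard similarity J_ij = x_ij / (x_ii + x_jj - x_ij).

    Diagonal is 1 for non-empty callers; entries with an empty union are NaN.
    """
    diag = np.diag(t.x).astype(float)
    union = diag[:, None] + diag[None, :] - t.x
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, t.x / np.where(union == 0, 1, union), np.nan)
    np.fill_diagonal(j, np.where(diag > 0, 1.0, np.nan))
    return j


def consensus_score(t: ToolCooccurrence) -> Optional[float]:
    """Consensus score from a co-occurrence matrix (total-sites diagonal).

    Callers with zero calls in scope are dropped first; with fewer than two
    contributing callers the score is undefined (``None``).
    """
    keep = [i for i in range(len(t.callers)) if t.x[i, i] > 0]
    n = len(keep)
    if n < 2:
        log.warning("consensus score undefined with %d non-empty callers", n)
        return None
    x = t.x[np.ix_(keep, keep)].astype(float)
    off = x.sum(axis=1) - np.diag(x)
    return float((off / np.diag(x)).sum() / (n * (n - 1)))


def consensus_score_from_sets(sets: Mapping[str, set],
                              diagonal: str = "total") -> Optional[float]:
    """Consensus score computed directly from per-caller site sets.

    ``diagonal="total"`` normalises each caller's overlap sum by its total
    site count (the default convention, CS in [0, 1]); ``"exclusive"``
    normalises by the caller's exclusive call count instead, an alternative
    reading of "tool-specific calls" that is unbounded above and undefined
    for callers with no exclusive sites.
    """
    labels = [c for c in sets if sets[c]]
    n = len(labels)
    if n < 2:
        return None
    union_others = {
        c: set().union(*(sets[d] for d in labels if d != c)) for c in labels
    }
    total = 0.0
    for c in labels:
        off_sum = sum(len(sets[c] & sets[d]) for d in labels if d != c)
        if diagonal == "total":
            denom = len(sets[c])
        elif diagonal == "exclusive":
            denom = len(sets[c] - union_others[c])
            if denom == 0:
                return None
        else:
            raise ValueError(f"unknown diagonal convention {diagonal!r}")
        total += off_sum / denom
    return total / (n * (n - 1))


def overlap_subjects(catalog: MutationCatalog) -> SubjectCooccurrence:
    """Subject-by-subject shared-site counts per caller, plus cross-caller CV.

    The CV of a subject pair is the sample standard deviation over callers of
    the pair's shared-site count divided by its mean; pairs with no
    co-occurrence under any caller are NaN (the report's grey cells).
    """
    if len(catalog.subjects) < 2:
        raise ValueError("subject co-occurrence needs at least 2 subjects")
    subjects = list(catalog.subjects)
    m = len(subjects)
    by_caller = catalog.subject_site_sets()
    per_caller: dict[str, np.ndarray] = {}
    for caller in catalog.callers:
        mat = np.zeros((m, m), dtype=np.int64)
        for i, p in enumerate(subjects):
            mat[i, i] = len(by_caller[caller][p])
            for j in range(i + 1, m):
                shared = len(by_caller[caller][p] & by_caller[caller][subjects[j]])
                mat[i, j] = mat[j, i] = shared
        per_caller[caller] = mat
    stack = np.stack([per_caller[c] for c in catalog.callers]).astype(float)
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        sd = stack.std(axis=0, ddof=1)
    else:
        sd = np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean == 0, 1, mean), np.nan)
    return SubjectCooccurrence(subjects, per_caller, cv)


def consensus_per_subject(catalog: MutationCatalog) -> list[ConsensusRecord]:
    """Per-subject CS, per-caller site counts and >=2-caller support fraction."""
    records: list[ConsensusRecord] = []
    for subject in catalog.subjects:
        t = overlap_tools(catalog, scope=subject)
        stats = site_statistics(catalog, scope=subject)
        cs = consensus_score(t)
        if stats.total_sites > 0:
            shared = sum(v for k, v in stats.histogram.items() if k >= 2)
            frac = shared / stats.total_sites
        else:
            frac = None
        records.append(ConsensusRecord(
            subject_id=subject, cs=cs, n_sites=stats.total_sites,
            caller_counts=stats.caller_counts, frac_k_ge_2=frac))
    return records
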