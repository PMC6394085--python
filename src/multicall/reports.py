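"""Canonical TSV report writers.

All reports are UTF-8, tab-separated, '.' decimal, ``NA`` for missing,
floats at 6 significant digits — so identical analyses yield byte-identical
files.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .consensus import (
    ConsensusRecord,
    OccurrenceStats,
    SubjectCooccurrence,
    ToolCooccurrence,
    jaccard_matrix,
)

FLOAT_FMT = "%.6g"


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep="NA",
                 float_format=FLOAT_FMT)


def occurrence_frame(stats: OccurrenceStats) -> pd.DataFrame:
    rows = []
    for caller, total in stats.caller_counts.items():
        rows.append({
            "caller": caller,
            "total": total,
            "exclusive_fraction": stats.exclusive_fraction[caller],
            "shared_fraction": stats.shared_fraction[caller],
        })
    return pd.DataFrame(rows, columns=["caller", "total", "exclusive_fraction",
                                       "shared_fraction"])


def histogram_frame(stats: OccurrenceStats) -> pd.DataFrame:
    return pd.DataFrame(
        [{"n_callers": k, "n_sites": v} for k, v in stats.histogram.items()],
        columns=["n_callers", "n_sites"])


def cooccurrence_frame(t: ToolCooccurrence) -> pd.DataFrame:
    return t.to_frame()


def jaccard_frame(t: ToolCooccurrence) -> pd.DataFrame:
    return pd.DataFrame(jaccard_matrix(t), index=t.callers, columns=t.callers)


def subject_consensus_frame(records: list[ConsensusRecord],
                            callers: list[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject": r.subject_id, "n_sites": r.n_sites}
        for caller in callers:
            row[f"n_{caller}"] = r.caller_counts.get(caller, 0)
        row["frac_k_ge_2"] = r.frac_k_ge_2
        row["CS"] = r.cs
        rows.append(row)
    cols = ["subject", "n_sites"] + [f"n_{c}" for c in callers] + \
        ["frac_k_ge_2", "CS"]
    return pd.DataFrame(rows, columns=cols)


def subject_cooccurrence_frames(sc: SubjectCooccurrence
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(long-format per-caller pair counts, CV matrix)."""
    rows = []
    m = len(sc.subjects)
    for caller, mat in sc.per_caller.items():
        for i in range(m):
            for j in range(i, m):
                rows.append({"caller": caller, "subject_a": sc.subjects[i],
                             "subject_b": sc.subjects[j],
                             "shared_sites": int(mat[i, j])})
    long = pd.DataFrame(rows, columns=["caller", "subject_a", "subject_b",
                                       "shared_sites"])
    cv = pd.DataFrame(sc.cv, index=sc.subjects, columns=sc.subjects)
    return long, cv
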