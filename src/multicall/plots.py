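"""Basic matplotlib renderings of the consensus reports (optional output)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .consensus import ConsensusRecord, OccurrenceStats, ToolCooccurrence


def plot_overall_consensus(stats: OccurrenceStats, path) -> None:
    """Per-caller totals split into exclusive vs shared calls."""
    callers = list(stats.caller_counts)
    totals = np.array([stats.caller_counts[c] for c in callers], dtype=float)
    excl = np.array([
        (stats.exclusive_fraction[c] or 0.0) * stats.caller_counts[c]
        for c in callers])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(callers, totals - excl, label="shared")
    ax.bar(callers, excl, bottom=totals - excl, label="exclusive")
    ax.set_ylabel("number of sites")
    ax.legend()
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cooccurrence_heatmap(t: ToolCooccurrence, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(t.x, cmap="viridis")
    ax.set_xticks(range(len(t.callers)), t.callers, rotation=45, ha="right")
    ax.set_yticks(range(len(t.callers)), t.callers)
    for i in range(len(t.callers)):
        for j in range(len(t.callers)):
            ax.text(j, i, str(t.x[i, j]), ha="center", va="center",
                    color="white", fontsize=8)
    fig.colorbar(im, ax=ax, label="shared sites")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_subject_cs(records: list[ConsensusRecord], path) -> None:
    subjects = [r.subject_id for r in records]
    cs = [np.nan if r.cs is None else r.cs for r in records]
    fig, ax = plt.subplots(figsize=(max(6, 0.2 * len(subjects)), 4))
    ax.bar(subjects, cs)
    ax.set_ylabel("consensus score")
    ax.set_ylim(0, 1.05)
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
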