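"""Gene-level views of the mutation catalogue.

Sites are assigned to genes from user-provided interval files (tab-delimited
1-based inclusive, or BED 0-based half-open). From the assignment we build,
per caller, a binary gene x subject mutation matrix, the gene mutation
frequency f (fraction of subjects with at least one mutated site in the
gene) and its dispersion across callers sd_f, plus the distance of each site
to the nearest exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .consensus import (
    OccurrenceStats,
    SubjectCooccurrence,
    ToolCooccurrence,
    cooccurrence_from_sets,
    occurrence_stats_from_sets,
)
from .core import MutationCatalog

log = logging.getLogger(__name__)


@dataclass
class GeneAnnotation:
    """Indexed gene (or exon) intervals, 1-based inclusive coordinates."""

    trees: dict[str, IntervalTree]
    n_rejected: int = 0

    @property
    def chroms(self) -> list[str]:
        return sorted(self.trees)

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        tree = self.trees.get(chrom)
        if tree is None:
            return set()
        # tree stores half-open [start, end+1) so point queries hit ends
        return {iv.data for iv in tree[pos]}

    def all_genes(self) -> list[str]:
        return sorted({iv.data for t in self.trees.values() for iv in t})

    def distance_to_nearest(self, chrom: str, pos: int) -> Optional[int]:
        """Bases strictly between pos and the nearest interval; 0 inside."""
        tree = self.trees.get(chrom)
        if tree is None or len(tree) == 0:
            return None
        if tree[pos]:
            return 0
        best = None
        for iv in tree:
            start, end = iv.begin, iv.end - 1  # back to inclusive
            gap = (start - pos) if pos < start else (pos - end)
            if best is None or gap < best:
                best = gap
        return best


def load_annotation(path, strip_chr: bool = True) -> GeneAnnotation:
    """Load gene/exon intervals from TSV (1-based inclusive) or BED.

    Files ending in ``.bed`` use the BED convention (0-based half-open) and
    are converted on load. Lines with start > end (after conversion) or
    non-numeric coordinates are skipped and counted. A header line is
    tolerated in TSV input.
    """
    is_bed = str(path).endswith(".bed")
    trees: dict[str, IntervalTree] = {}
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                rejected += 1
                continue
            chrom, start_s, end_s, gene = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                if lineno == 1 and not is_bed:
                    continue  # header
                rejected += 1
                continue
            if is_bed:
                start, end = start + 1, end  # half-open -> 1-based inclusive
            if start > end:
                rejected += 1
                log.debug("%s line %d: start > end, skipped", path, lineno)
                continue
            if strip_chr and chrom.startswith("chr"):
                chrom = chrom[3:]
            trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, gene)
    if rejected:
        log.warning("%s: %d malformed interval lines skipped", path, rejected)
    return GeneAnnotation(trees, rejected)


def annotate_sites(catalog: MutationCatalog,
                   ann: GeneAnnotation) -> dict[str, set[str]]:
    """Map every site key to the set of genes whose interval contains it.

    INDELs are located at the position of their first reference base. Sites
    in no interval map to the empty set; overlapping genes all receive the
    site.
    """
    mapping: dict[str, set[str]] = {}
    for (_, key) in catalog.calls:
        if key in mapping:
            continue
        chrom, pos, _, _ = key.split(":", 3)
        mapping[key] = ann.genes_at(chrom, int(pos))
    return mapping


@dataclass
class GeneMutationMatrix:
    """Binary gene x subject matrices per caller with f and sd_f."""

    matrices: dict[str, pd.DataFrame]  # caller -> genes x subjects of 0/1
    freq: pd.DataFrame  # genes x (callers + 'union'), values of f
    sd_f: pd.Series  # per gene, sample SD of f across callers


def _gene_subject_sets(catalog: MutationCatalog,
                       site_genes: dict[str, set[str]]
                       ) -> dict[str, set[tuple[str, str]]]:
    """caller -> set of (subject, gene) units with >= 1 annotated site."""
    out: dict[str, set[tuple[str, str]]] = {c: set() for c in catalog.callers}
    for (subj, key), entry in catalog.calls.items():
        for gene in site_genes.get(key, ()):
            for caller in entry:
                out[caller].add((subj, gene))
    return out


def gene_mutation(catalog: MutationCatalog,
                  ann: GeneAnnotation) -> GeneMutationMatrix:
    """Per-caller gene x subject mutation matrices, f and sd_f.

    f is computed over all catalogue subjects (a subject with no mutation in
    the gene under a caller contributes a 0). The union column treats a gene
    as mutated when any caller reports a site in it.
    """
    site_genes = annotate_sites(catalog, ann)
    genes = sorted({g for gs in site_genes.values() for g in gs})
    subjects = list(catalog.subjects)
    units = _gene_subject_sets(catalog, site_genes)
    matrices: dict[str, pd.DataFrame] = {}
    for caller in catalog.callers:
        mat = pd.DataFrame(0, index=genes, columns=subjects, dtype=np.int8)
        for subj, gene in units[caller]:
            mat.loc[gene, subj] = 1
        matrices[caller] = mat
    n_subj = max(len(subjects), 1)
    freq = pd.DataFrame(index=genes)
    for caller in catalog.callers:
        freq[caller] = matrices[caller].sum(axis=1) / n_subj
    union_units = set().union(*units.values()) if units else set()
    union_mat = pd.DataFrame(0, index=genes, columns=subjects, dtype=np.int8)
    for subj, gene in union_units:
        union_mat.loc[gene, subj] = 1
    freq["union"] = union_mat.sum(axis=1) / n_subj
    caller_cols = freq[list(catalog.callers)]
    if len(catalog.callers) > 1:
        sd_f = caller_cols.std(axis=1, ddof=1)
    else:
        sd_f = pd.Series(0.0, index=genes)
    sd_f.name = "sd_f"
    return GeneMutationMatrix(matrices, freq, sd_f)


def gene_level_overlaps(catalog: MutationCatalog, ann: GeneAnnotation
                        ) -> tuple[OccurrenceStats, ToolCooccurrence,
                                   Optional[SubjectCooccurrence]]:
    """Consensus machinery with (subject, gene) as the unit of identity."""
    site_genes = annotate_sites(catalog, ann)
    units = _gene_subject_sets(catalog, site_genes)
    stats = occurrence_stats_from_sets(catalog.callers, units, "cohort")
    cooc = cooccurrence_from_sets(catalog.callers, units, "cohort")
    subj_cooc = None
    if len(catalog.subjects) >= 2:
        m = len(catalog.subjects)
        idx = {s: i for i, s in enumerate(catalog.subjects)}
        per_caller: dict[str, np.ndarray] = {}
        for caller in catalog.callers:
            gene_sets = {s: set() for s in catalog.subjects}
            for subj, gene in units[caller]:
                gene_sets[subj].add(gene)
            mat = np.zeros((m, m), dtype=np.int64)
            for i, p in enumerate(catalog.subjects):
                mat[i, i] = len(gene_sets[p])
                for j in range(i + 1, m):
                    q = catalog.subjects[j]
                    mat[i, j] = mat[j, i] = len(gene_sets[p] & gene_sets[q])
            per_caller[caller] = mat
        stack = np.stack([per_caller[c] for c in catalog.callers]).astype(float)
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > 0, sd / np.where(mean == 0, 1, mean), np.nan)
        subj_cooc = SubjectCooccurrence(list(catalog.subjects), per_caller, cv)
    return stats, cooc, subj_cooc


def distance_to_exon(catalog: MutationCatalog,
                     exons: GeneAnnotation) -> dict[str, Optional[int]]:
    """Per site key, bp distance to the nearest exon (0 inside an exon).

    Adjacent to an exon boundary counts as distance 1; chromosomes without
    any exon yield ``None``.
    """
    out: dict[str, Optional[int]] = {}
    for (_, key) in catalog.calls:
        if key in out:
            continue
        chrom, pos, _, _ = key.split(":", 3)
        out[key] = exons.distance_to_nearest(chrom, int(pos))
    return out
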