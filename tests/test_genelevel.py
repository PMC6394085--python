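"""Tests for gene annotation, mutation matrices, f/sd_f and exon distance."""

import numpy as np
import pandas as pd
import pytest

from multicall.genelevel import (
    GeneAnnotation,
    annotate_sites,
    distance_to_exon,
    gene_level_overlaps,
    gene_mutation,
    load_annotation,
)
from multicall.consensus import overlap_tools, site_statistics

from conftest import catalog_from_sets, make_call
from multicall.core import MutationCatalog


def write_intervals(tmp_path, rows, name="genes.tsv", header=True):
    path = tmp_path / name
    lines = ["chrom\tstart\tend\tgene"] if header else []
    lines += ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadAnnotation:
    def test_tsv_disjoint_intervals(self, tmp_path):
        ann = load_annotation(write_intervals(tmp_path, [
            ("1", 100, 200, "G1"), ("1", 300, 400, "G2"), ("2", 10, 50, "G3")]))
        assert ann.all_genes() == ["G1", "G2", "G3"]
        assert ann.genes_at("1", 150) == {"G1"}
        assert ann.genes_at("1", 200) == {"G1"}  # inclusive end
        assert ann.genes_at("1", 201) == set()

    def test_bed_half_open_conversion(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("1\t99\t200\tG1\n")
        ann = load_annotation(path)
        assert ann.genes_at("1", 100) == {"G1"}
        assert ann.genes_at("1", 99) == set()
        assert ann.genes_at("1", 200) == {"G1"}

    def test_malformed_lines_counted(self, tmp_path):
        ann = load_annotation(write_intervals(tmp_path, [
            ("1", 100, 200, "G1"), ("1", 500, 400, "BAD"), ("1", "x", 9, "BAD2")]))
        assert ann.n_rejected == 2
        assert ann.all_genes() == ["G1"]


class TestAnnotateSites:
    def _ann(self, tmp_path):
        return load_annotation(write_intervals(tmp_path, [
            ("1", 100, 200, "G1"), ("1", 150, 300, "G2")]))

    def test_point_and_overlapping_and_intergenic(self, tmp_path):
        ann = self._ann(tmp_path)
        cat = catalog_from_sets({"a": {"S1": {119, 179, 999}}})  # +1 shift
        mapping = annotate_sites(cat, ann)
        assert mapping["1:120:A:T"] == {"G1"}
        assert mapping["1:180:A:T"] == {"G1", "G2"}
        assert mapping["1:1000:A:T"] == set()


class TestGeneMutation:
    def test_frequency_simple(self, tmp_path):
        ann = load_annotation(write_intervals(tmp_path, [("1", 1, 1000, "G1")]))
        data = {"a": {f"S{i}": ({5} if i < 3 else set()) for i in range(10)}}
        gm = gene_mutation(catalog_from_sets(data), ann)
        assert gm.freq.loc["G1", "a"] == pytest.approx(0.3)

    def test_sd_zero_when_callers_identical(self, tmp_path):
        ann = load_annotation(write_intervals(tmp_path, [("1", 1, 1000, "G1")]))
        sites = {"S1": {10, 20}, "S2": {30}}
        cat = catalog_from_sets({"a": sites, "b": sites, "c": sites})
        gm = gene_mutation(cat, ann)
        assert gm.sd_f.loc["G1"] == 0.0

    def test_sd_f_sample_standard_deviation(self, tmp_path):
        """f = (0.1, 0.2, 0.3, 0.4) across 4 callers -> sd_f ~ 0.1291."""
        ann = load_annotation(write_intervals(tmp_path, [("1", 1, 1000, "G1")]))
        data = {}
        for c_idx, caller in enumerate(["a", "b", "c", "d"]):
            n_mut = c_idx + 1  # 1..4 of 10 subjects
            data[caller] = {f"S{i}": ({5} if i < n_mut else set())
                            for i in range(10)}
        gm = gene_mutation(catalog_from_sets(data), ann)
        expected = np.std([0.1, 0.2, 0.3, 0.4], ddof=1)
        assert gm.sd_f.loc["G1"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.1291, abs=5e-5)

    def test_f_recovery_planted_probabilities(self, tmp_path):
        """Observed f within 3 binomial SEs of planted per-gene probabilities."""
        rng = np.random.default_rng(11)
        n_subjects, genes = 100, {f"G{g}": 0.05 + 0.08 * g for g in range(10)}
        rows = [("1", 1000 * i + 1, 1000 * i + 500, g)
                for i, g in enumerate(genes)]
        ann = load_annotation(write_intervals(tmp_path, rows))
        cat = MutationCatalog()
        for s in range(n_subjects):
            for i, (gene, p) in enumerate(genes.items()):
                if rng.random() < p:
                    pos = 1000 * i + int(rng.integers(1, 500))
                    for caller in ("a", "b"):
                        cat.add(make_call(f"S{s:03d}", caller, pos=pos))
        gm = gene_mutation(cat, ann)
        for i, (gene, p) in enumerate(genes.items()):
            se = np.sqrt(p * (1 - p) / n_subjects)
            for caller in ("a", "b"):
                assert abs(gm.freq.loc[gene, caller] - p) <= 3 * se

    def test_sd_f_invariant_under_caller_permutation(self, tmp_path):
        ann = load_annotation(write_intervals(tmp_path, [("1", 1, 2000, "G1")]))
        data = {"a": {"S1": {10}, "S2": set()},
                "b": {"S1": {10}, "S2": {20}},
                "c": {"S1": set(), "S2": set()}}
        sd1 = gene_mutation(catalog_from_sets(data), ann).sd_f
        permuted = {k: data[k] for k in ["c", "a", "b"]}
        sd2 = gene_mutation(catalog_from_sets(permuted), ann).sd_f
        pd.testing.assert_series_equal(sd1, sd2)


class TestGeneLevelOverlaps:
    def test_gene_unit_rescues_site_disagreement(self, tmp_path):
        """Two callers hitting different sites of one gene co-occur at gene level."""
        ann = load_annotation(write_intervals(tmp_path, [("1", 1, 1000, "G1")]))
        cat = catalog_from_sets({"a": {"S1": {100}}, "b": {"S1": {200}}})
        assert overlap_tools(cat).x[0, 1] == 0
        _, cooc, _ = gene_level_overlaps(cat, ann)
        assert cooc.x[0, 1] == 1

    def test_no_annotated_sites_empty(self, tmp_path):
        ann = load_annotation(write_intervals(tmp_path, [("9", 1, 10, "G1")]))
        cat = catalog_from_sets({"a": {"S1": {100}}, "b": {"S1": {100}}})
        stats, cooc, _ = gene_level_overlaps(cat, ann)
        assert stats.total_sites == 0
        assert (cooc.x == 0).all()

    def test_degenerates_to_site_level_one_site_per_gene(self, tmp_path):
        """With exactly one site per gene, gene stats equal site stats."""
        rng = np.random.default_rng(5)
        positions = sorted(rng.choice(np.arange(1, 10_000, 10), 40, replace=False))
        rows = [("1", int(p), int(p), f"G{p}") for p in positions]
        ann = load_annotation(write_intervals(tmp_path, rows))
        data = {c: {"S1": set(), "S2": set()} for c in ["a", "b", "c"]}
        for p in positions:
            for c in data:
                for s in ("S1", "S2"):
                    if rng.random() < 0.5:
                        data[c][s].add(int(p) - 1)  # -1 offsets conftest's +1
        cat = catalog_from_sets(data)
        site_stats = site_statistics(cat)
        gene_stats, gene_cooc, _ = gene_level_overlaps(cat, ann)
        assert gene_stats.histogram == site_stats.histogram
        assert (gene_cooc.x == overlap_tools(cat).x).all()


class TestDistanceToExon:
    def _exons(self, tmp_path):
        return load_annotation(write_intervals(tmp_path, [
            ("1", 200, 300, "E1"), ("1", 500, 600, "E2")], name="exons.tsv"))

    def test_inside_exon_zero(self, tmp_path):
        exons = self._exons(tmp_path)
        assert exons.distance_to_nearest("1", 250) == 0

    def test_upstream_gap(self, tmp_path):
        """pos 150, nearest exon [200, 300] -> distance 50."""
        exons = self._exons(tmp_path)
        assert exons.distance_to_nearest("1", 150) == 50

    def test_adjacent_base_distance_one(self, tmp_path):
        exons = self._exons(tmp_path)
        assert exons.distance_to_nearest("1", 199) == 1
        assert exons.distance_to_nearest("1", 301) == 1

    def test_between_exons_takes_minimum(self, tmp_path):
        exons = self._exons(tmp_path)
        assert exons.distance_to_nearest("1", 460) == 40

    def test_chromosome_without_exons_missing(self, tmp_path):
        exons = self._exons(tmp_path)
        cat = catalog_from_sets({"a": {"S1": {249}}})
        cat.add(make_call("S1", "a", chrom="7", pos=42))
        dist = distance_to_exon(cat, exons)
        assert dist["1:250:A:T"] == 0
        assert dist["7:42:A:T"] is None
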