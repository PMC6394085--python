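"""Tests for occurrence statistics, co-occurrence matrices and the CS."""

from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multicall.consensus import (
    ToolCooccurrence,
    consensus_per_subject,
    consensus_score,
    consensus_score_from_sets,
    cooccurrence_from_sets,
    jaccard_matrix,
    occurrence_stats_from_sets,
    overlap_subjects,
    overlap_tools,
    site_statistics,
)

from conftest import catalog_from_sets


def brute_force_cs(sets: dict[str, set]) -> float | None:
    """Direct evaluation of CS = sum_i((1/x_ii) sum_{j!=i} x_ij) / (n(n-1))."""
    labels = [c for c, s in sets.items() if s]
    n = len(labels)
    if n < 2:
        return None
    total = 0.0
    for i in labels:
        total += sum(len(sets[i] & sets[j]) for j in labels if j != i) / len(sets[i])
    return total / (n * (n - 1))


sets_strategy = st.dictionaries(
    keys=st.sampled_from(["c1", "c2", "c3", "c4", "c5"]),
    values=st.sets(st.integers(min_value=0, max_value=99), max_size=100),
    min_size=3, max_size=5,
)


class TestSiteStatistics:
    def test_single_caller(self):
        cat = catalog_from_sets({"muse": {"S1": set(range(7))}})
        stats = site_statistics(cat)
        assert stats.histogram == {1: 7}
        assert stats.exclusive_fraction["muse"] == 1.0

    def test_perfect_consensus(self):
        sites = {"S1": {1, 2, 3, 4, 5}}
        cat = catalog_from_sets({c: sites for c in ["muse", "mutect2", "varscan2"]})
        stats = site_statistics(cat)
        assert stats.histogram == {3: 5}
        assert all(v == 0.0 for v in stats.exclusive_fraction.values())

    def test_partial_overlap(self, two_caller_catalog):
        stats = site_statistics(two_caller_catalog)
        assert stats.histogram == {1: 2, 2: 2}
        assert stats.total_sites == 4
        assert stats.exclusive_fraction["mutect2"] == pytest.approx(1 / 3)
        assert stats.exclusive_fraction["varscan2"] == pytest.approx(1 / 3)

    @settings(max_examples=50, deadline=None)
    @given(sets=sets_strategy)
    def test_histogram_identities(self, sets):
        labels = list(sets)
        stats = occurrence_stats_from_sets(labels, sets)
        assert sum(stats.histogram.values()) == stats.total_sites
        assert sum(k * v for k, v in stats.histogram.items()) == \
            sum(len(s) for s in sets.values())


class TestOverlapTools:
    def test_pair_example(self, two_caller_catalog):
        t = overlap_tools(two_caller_catalog)
        assert list(np.diag(t.x)) == [3, 3]
        assert t.x[0, 1] == 2

    def test_empty_scope_zero_matrix(self, two_caller_catalog):
        t = overlap_tools(two_caller_catalog, scope="missing_subject")
        assert (t.x == 0).all()

    @settings(max_examples=50, deadline=None)
    @given(sets=sets_strategy)
    def test_matches_brute_force_and_invariants(self, sets):
        labels = list(sets)
        t = cooccurrence_from_sets(labels, sets)
        assert (t.x == t.x.T).all()
        for i, j in combinations(range(len(labels)), 2):
            expected = len(sets[labels[i]] & sets[labels[j]])
            assert t.x[i, j] == expected
            assert t.x[i, j] <= min(t.x[i, i], t.x[j, j])


class TestJaccard:
    def test_half_overlap(self):
        t = ToolCooccurrence(["a", "b"], np.array([[3, 2], [2, 3]]))
        assert jaccard_matrix(t)[0, 1] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        ident = ToolCooccurrence(["a", "b"], np.array([[4, 4], [4, 4]]))
        assert jaccard_matrix(ident)[0, 1] == 1.0
        disj = ToolCooccurrence(["a", "b"], np.array([[4, 0], [0, 5]]))
        assert jaccard_matrix(disj)[0, 1] == 0.0

    def test_empty_union_is_missing(self):
        t = ToolCooccurrence(["a", "b"], np.zeros((2, 2), dtype=int))
        j = jaccard_matrix(t)
        assert np.isnan(j[0, 1]) and np.isnan(j[0, 0])

    @settings(max_examples=50, deadline=None)
    @given(sets=sets_strategy)
    def test_bounds_and_identity(self, sets):
        labels = list(sets)
        j = jaccard_matrix(cooccurrence_from_sets(labels, sets))
        finite = j[np.isfinite(j)]
        assert ((finite >= 0) & (finite <= 1)).all()
        for a, b in combinations(range(len(labels)), 2):
            if sets[labels[a]] or sets[labels[b]]:
                is_one = j[a, b] == 1.0
                assert is_one == (sets[labels[a]] == sets[labels[b]] != set())


class TestConsensusScore:
    def test_perfect_consensus_is_one(self):
        s = set(range(10))
        t = cooccurrence_from_sets(["a", "b", "c"], {"a": s, "b": s, "c": s})
        assert consensus_score(t) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        t = cooccurrence_from_sets(
            ["a", "b", "c"],
            {"a": {1, 2}, "b": {3, 4}, "c": {5, 6}})
        assert consensus_score(t) == 0.0

    def test_hand_case(self):
        """diag (10,20,10), x_AB=5, x_AC=0, x_BC=10 -> (5/10+15/20+10/10)/6."""
        x = np.array([[10, 5, 0], [5, 20, 10], [0, 10, 10]])
        t = ToolCooccurrence(["a", "b", "c"], x)
        assert consensus_score(t) == pytest.approx(0.375, abs=1e-12)

    def test_zero_call_callers_dropped(self):
        s = set(range(5))
        t = cooccurrence_from_sets(["a", "b", "empty"],
                                   {"a": s, "b": s, "empty": set()})
        assert consensus_score(t) == pytest.approx(1.0)

    def test_undefined_below_two_callers(self):
        t = cooccurrence_from_sets(["a", "b"], {"a": {1}, "b": set()})
        assert consensus_score(t) is None

    @settings(max_examples=100, deadline=None)
    @given(sets=sets_strategy)
    def test_oracle_equivalence(self, sets):
        labels = list(sets)
        got = consensus_score(cooccurrence_from_sets(labels, sets))
        expected = brute_force_cs(sets)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= got <= 1.0

    @settings(max_examples=30, deadline=None)
    @given(sets=sets_strategy)
    def test_permutation_invariance(self, sets):
        labels = list(sets)
        base = consensus_score(cooccurrence_from_sets(labels, sets))
        for perm in list(permutations(labels))[:6]:
            got = consensus_score(cooccurrence_from_sets(list(perm), sets))
            if base is None:
                assert got is None
            else:
                assert got == pytest.approx(base, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(sets=sets_strategy, new_site=st.integers(min_value=1000, max_value=2000))
    def test_shared_site_never_decreases_cs(self, sets, new_site):
        labels = [c for c in sets if sets[c]]
        if len(labels) < 2:
            return
        before = consensus_score(cooccurrence_from_sets(labels, sets))
        grown = {c: sets[c] | {new_site} for c in labels}
        after = consensus_score(cooccurrence_from_sets(labels, grown))
        assert after >= before - 1e-12

    @settings(max_examples=50, deadline=None)
    @given(sets=sets_strategy, new_site=st.integers(min_value=1000, max_value=2000))
    def test_exclusive_site_never_increases_cs(self, sets, new_site):
        labels = [c for c in sets if sets[c]]
        if len(labels) < 2:
            return
        before = consensus_score(cooccurrence_from_sets(labels, sets))
        grown = dict(sets)
        grown[labels[0]] = sets[labels[0]] | {new_site}
        after = consensus_score(cooccurrence_from_sets(labels, grown))
        assert after <= before + 1e-12

    def test_exclusive_diagonal_option(self):
        sets = {"a": {1, 2, 3, 4}, "b": {1, 2, 5}}
        # exclusive counts: a -> {3,4} (2), b -> {5} (1); overlap 2
        expected = (2 / 2 + 2 / 1) / 2
        assert consensus_score_from_sets(sets, diagonal="exclusive") == \
            pytest.approx(expected)
        assert consensus_score_from_sets(sets, diagonal="total") == \
            pytest.approx(brute_force_cs(sets), abs=1e-12)


class TestOverlapSubjects:
    def _catalog(self, counts):
        """Three callers; subjects P and Q share `counts[c]` sites under caller c."""
        data = {}
        for idx, (caller, k) in enumerate(counts.items()):
            shared = set(range(k))
            data[caller] = {"P": shared | {100 + idx}, "Q": shared | {200 + idx}}
        return catalog_from_sets(data)

    def test_constant_counts_cv_zero(self):
        cat = self._catalog({"a": 4, "b": 4, "c": 4})
        sc = overlap_subjects(cat)
        assert sc.cv[0, 1] == pytest.approx(0.0)

    def test_sample_sd_cv(self):
        """Counts (2,4,6) across callers: sd=2, mean=4 -> CV=0.5."""
        cat = self._catalog({"a": 2, "b": 4, "c": 6})
        sc = overlap_subjects(cat)
        assert sc.per_caller["a"][0, 1] == 2
        assert sc.cv[0, 1] == pytest.approx(0.5)

    def test_no_cooccurrence_is_missing(self):
        cat = catalog_from_sets({
            "a": {"P": {1}, "Q": {2}},
            "b": {"P": {3}, "Q": {4}},
        })
        sc = overlap_subjects(cat)
        assert np.isnan(sc.cv[0, 1])

    def test_single_subject_rejected(self):
        cat = catalog_from_sets({"a": {"P": {1, 2}}})
        with pytest.raises(ValueError):
            overlap_subjects(cat)


class TestConsensusPerSubject:
    def test_perfect_and_disjoint_subjects(self):
        cat = catalog_from_sets({
            "a": {"PERF": {1, 2, 3}, "DISJ": {10, 11}},
            "b": {"PERF": {1, 2, 3}, "DISJ": {20, 21}},
        })
        records = {r.subject_id: r for r in consensus_per_subject(cat)}
        assert records["PERF"].cs == pytest.approx(1.0)
        assert records["PERF"].frac_k_ge_2 == 1.0
        assert records["DISJ"].cs == 0.0
        assert records["DISJ"].frac_k_ge_2 == 0.0

    def test_matches_per_subject_oracle(self):
        rng = np.random.default_rng(42)
        data = {c: {} for c in ["a", "b", "c"]}
        for subj in ["S1", "S2", "S3"]:
            for c in data:
                data[c][subj] = set(rng.integers(0, 50, size=rng.integers(5, 30)).tolist())
        cat = catalog_from_sets(data)
        for rec in consensus_per_subject(cat):
            raw = {c: data[c][rec.subject_id] for c in data}
            assert rec.cs == pytest.approx(brute_force_cs(raw), abs=1e-12)
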