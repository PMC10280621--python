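import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladolink import (
    Clustering,
    complete_graph,
    comparison_report,
    cut_by_count,
    cut_by_threshold,
    distance_matrix,
    fscore,
    minimum_spanning_tree,
    mst_to_cladogram,
    single_linkage,
)

IDS = ["a", "b", "c", "d", "e", "f"]
partitions = st.lists(
    st.integers(min_value=0, max_value=3), min_size=6, max_size=6
).map(
    lambda labels: Clustering(
        {
            i: sorted(set(labels)).index(l)
            for i, l in zip(IDS, labels)
        }
    )
)


class TestCuts:
    def test_threshold_below_all_heights_gives_singletons(self, acgt_set):
        dend = single_linkage(distance_matrix(acgt_set))
        assert cut_by_threshold(dend, 0.9).k == 4

    def test_threshold_at_max_height_gives_one_cluster(self, acgt_set):
        dend = single_linkage(distance_matrix(acgt_set))
        assert cut_by_threshold(dend, 1).k == 1

    def test_prop2_threshold_two_isolates_outlier(self, prop2_set):
        dend = single_linkage(distance_matrix(prop2_set))
        cut = cut_by_threshold(dend, 2)
        parts = {frozenset(c) for c in cut.clusters()}
        assert parts == {
            frozenset({"1110000", "1100000", "0000000"}),
            frozenset({"1111111"}),
        }

    def test_count_extremes(self, prop2_set):
        dend = single_linkage(distance_matrix(prop2_set))
        assert cut_by_count(dend, len(prop2_set)).k == len(prop2_set)
        assert cut_by_count(dend, 1).k == 1

    def test_prop2_count_two_undoes_last_merge(self, prop2_set):
        dend = single_linkage(distance_matrix(prop2_set))
        cut = cut_by_count(dend, 2)
        parts = {frozenset(c) for c in cut.clusters()}
        assert frozenset({"1111111"}) in parts

    def test_count_out_of_range(self, prop2_set):
        dend = single_linkage(distance_matrix(prop2_set))
        with pytest.raises(ValueError):
            cut_by_count(dend, 0)
        with pytest.raises(ValueError):
            cut_by_count(dend, 5)

    def test_cladogram_cut_matches_dendrogram_cut_on_prop2(self, prop2_set):
        """Both trees isolate the distant outlier at k = 2."""
        dend = single_linkage(distance_matrix(prop2_set))
        clad = mst_to_cladogram(
            minimum_spanning_tree(complete_graph(prop2_set)), prop2_set
        )
        a = cut_by_count(dend, 2)
        b = cut_by_count(clad, 2)
        assert fscore(a, b) == 1.0

    def test_cladogram_cut_extremes(self, acgt_set):
        clad = mst_to_cladogram(
            minimum_spanning_tree(complete_graph(acgt_set)), acgt_set
        )
        assert cut_by_count(clad, 1).k == 1


class TestFscore:
    def test_identical_partitions_score_one(self):
        A = Clustering({"a": 0, "b": 0, "c": 1, "d": 1})
        assert fscore(A, A) == 1.0
        assert fscore(A, A, variant="matching") == 1.0

    def test_singletons_vs_one_cluster_is_zero(self):
        A = Clustering({x: i for i, x in enumerate("abcd")})
        B = Clustering({x: 0 for x in "abcd"})
        assert fscore(A, B) == 0.0

    def test_crossed_pairs_share_no_co_clustered_pair(self):
        A = Clustering({"a": 0, "b": 0, "c": 1, "d": 1})
        B = Clustering({"a": 0, "c": 0, "b": 1, "d": 1})
        assert fscore(A, B) == 0.0

    def test_mismatched_id_sets_rejected(self):
        A = Clustering({"a": 0, "b": 0})
        B = Clustering({"a": 0, "c": 0})
        with pytest.raises(ValueError):
            fscore(A, B)

    def test_unknown_variant_rejected(self):
        A = Clustering({"a": 0, "b": 0})
        with pytest.raises(ValueError):
            fscore(A, A, variant="bogus")

    @settings(derandomize=True, max_examples=150)
    @given(partitions, partitions)
    def test_symmetric_bounded_and_one_iff_equal(self, A, B):
        for variant in ("pairwise", "matching"):
            s = fscore(A, B, variant=variant)
            assert 0.0 <= s <= 1.0
            assert s == fscore(B, A, variant=variant)
        same = {frozenset(c) for c in A.clusters()} == {
            frozenset(c) for c in B.clusters()
        }
        assert (fscore(A, B) == 1.0) == same

    @settings(derandomize=True, max_examples=60)
    @given(partitions, partitions, st.permutations(list(range(4))))
    def test_invariant_under_cluster_relabeling(self, A, B, perm):
        order: dict[int, int] = {}
        renamed = {}
        for i, c in A.assignment.items():
            p = perm[c]
            if p not in order:
                order[p] = len(order)
            renamed[i] = order[p]
        Ap = Clustering(renamed)
        assert fscore(Ap, A) == 1.0
        assert fscore(Ap, B) == fscore(A, B)
        # matching variant sums per-cluster terms whose order depends on the
        # index permutation; equal up to float summation order
        assert fscore(Ap, B, "matching") == pytest.approx(
            fscore(A, B, "matching"), abs=1e-12
        )

    def test_comparison_report_unit_diagonal(self, prop2_set):
        dend = single_linkage(distance_matrix(prop2_set))
        cuts = {
            "k2": cut_by_count(dend, 2),
            "k4": cut_by_count(dend, 4),
        }
        report = comparison_report(cuts)
        assert report["k2"]["k2"] == report["k4"]["k4"] == 1.0
        assert report["k2"]["k4"] == report["k4"]["k2"]


def _same(A, B):
    return {frozenset(c) for c in A.clusters()} == {
        frozenset(c) for c in B.clusters()
    }
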