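import networkx as nx
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from cladolink import (
    SimulationConfig,
    complete_graph,
    cut_by_threshold,
    distance_matrix,
    fitch_min_weight,
    labeled_single_linkage,
    merge_tree,
    minimum_spanning_tree,
    normalize_heights,
    parsimony_weight,
    sequence_set,
    simulate_tree_sequences,
    single_linkage,
    validate_cladogram,
)


class TestSingleLinkage:
    def test_acgt_merges_all_at_height_one(self, acgt_set):
        dend = single_linkage(distance_matrix(acgt_set))
        assert len(dend.merges) == 3
        assert dend.heights == [1, 1, 1]
        assert normalize_heights(dend, 4).heights == [0.25, 0.25, 0.25]

    def test_prop2_merge_order_and_heights(self, prop2_set):
        dend = single_linkage(distance_matrix(prop2_set))
        assert dend.heights == [1, 2, 4]
        # first merge joins the two chain neighbours at distance 1
        first = dend.merges[0]
        joined = {dend.ids[first.a], dend.ids[first.b]}
        assert joined == {"1110000", "1100000"}
        # the outlier joins last
        assert dend.merges[-1].pair[1] == "1111111" or \
            dend.merges[-1].pair[0] == "1111111"

    def test_two_points(self):
        S = sequence_set(["AAA", "TTA"])
        dend = single_linkage(distance_matrix(S))
        assert len(dend.merges) == 1 and dend.heights == [2]

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            single_linkage(distance_matrix(sequence_set(["AAA"])))

    @pytest.mark.parametrize("seed", range(10))
    def test_heights_match_scipy_single_linkage(self, seed):
        """Merge heights equal scipy's single-linkage heights (both equal
        the sorted MST edge weights)."""
        cfg = SimulationConfig(leaves=4 + seed % 5, n=8, p=0.3, seed=seed)
        S, _ = simulate_tree_sequences(cfg)
        D = distance_matrix(S)
        dend = single_linkage(D)
        Z = scipy_linkage(squareform(D.values), method="single")
        assert dend.heights == pytest.approx(Z[:, 2].tolist())
        mst_weights = sorted(
            w
            for _, _, w in minimum_spanning_tree(complete_graph(S)).edges
        )
        assert dend.heights == mst_weights

    @pytest.mark.parametrize("seed", range(10))
    def test_heights_are_non_decreasing(self, seed):
        cfg = SimulationConfig(leaves=5 + seed % 4, n=10, p=0.4, seed=50 + seed)
        S, _ = simulate_tree_sequences(cfg)
        h = single_linkage(distance_matrix(S)).heights
        assert h == sorted(h)


def test_normalize_rejects_zero():
    S = sequence_set(["AA", "AT"])
    dend = single_linkage(distance_matrix(S))
    with pytest.raises(ValueError):
        normalize_heights(dend, 0)
    assert normalize_heights(dend, 1).heights == dend.heights


@pytest.mark.parametrize("seed", range(8))
def test_threshold_cut_equals_mst_component_cut(seed):
    """Cutting the dendrogram at t partitions S exactly like deleting all
    MST edges heavier than t."""
    cfg = SimulationConfig(leaves=4 + seed % 5, n=8, p=0.35, seed=200 + seed)
    S, _ = simulate_tree_sequences(cfg)
    dend = single_linkage(distance_matrix(S))
    T = minimum_spanning_tree(complete_graph(S))
    weights = sorted({w for _, _, w in T.edges})
    thresholds = [w for w in weights] + [w + 0.5 for w in weights] + [-1]
    for t in thresholds:
        cut = cut_by_threshold(dend, t)
        pruned = nx.Graph()
        pruned.add_nodes_from(T.vertices)
        pruned.add_edges_from(
            (u, v) for u, v, w in T.edges if w <= t
        )
        mst_parts = {
            frozenset(c) for c in nx.connected_components(pruned)
        }
        dend_parts = {frozenset(c) for c in cut.clusters()}
        assert dend_parts == mst_parts, f"threshold {t}"


class TestLabeledSingleLinkage:
    def test_all_labels_in_s_and_valid(self, prop2_set):
        result = labeled_single_linkage(prop2_set)
        labels = {n.label for n in result.tree.nodes()}
        assert labels <= set(prop2_set.seqs)
        assert validate_cladogram(result.tree, prop2_set) == []

    def test_prop2_weight_strictly_exceeds_mst(self, prop2_set):
        result = labeled_single_linkage(prop2_set)
        w = parsimony_weight(result.tree)
        assert w >= 8 > 7  # no labeling of this topology reaches MST weight

    def test_acgt_weight_at_least_mst(self, acgt_set):
        result = labeled_single_linkage(acgt_set)
        assert parsimony_weight(result.tree) >= 3

    def test_two_points_cherry(self):
        S = sequence_set(["AAA", "TTA"])
        result = labeled_single_linkage(S)
        assert parsimony_weight(result.tree) == 2
        assert sorted(l.name for l in result.tree.leaves()) == ["AAA", "TTA"]

    def test_topology_mirrors_dendrogram(self, prop2_set):
        result = labeled_single_linkage(prop2_set)
        ours = {
            frozenset(l.name for l in _leaves_under(c))
            for _, c in result.tree.edges()
        }
        dend_tree = result.dendrogram.as_cladogram()
        theirs = {
            frozenset(l.name for l in _leaves_under(c))
            for _, c in dend_tree.edges()
        }
        assert ours == theirs

    def test_root_label_provenance_recorded(self, prop2_set):
        result = labeled_single_linkage(prop2_set)
        assert result.provenance[-1][0] == "root"

    @pytest.mark.parametrize("seed", range(10))
    def test_heuristic_weight_bounded_below_by_small_parsimony(self, seed):
        cfg = SimulationConfig(leaves=4 + seed % 4, n=8, p=0.3, seed=300 + seed)
        S, _ = simulate_tree_sequences(cfg)
        result = labeled_single_linkage(S)
        topo = merge_tree(result.dendrogram)
        assert parsimony_weight(result.tree) >= fitch_min_weight(topo, S)
        assert validate_cladogram(result.tree, S) == []


def _leaves_under(node):
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            yield cur
        stack.extend(cur.children)
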