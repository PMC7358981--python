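import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from topodmn import (
    betti0_at,
    betti0_curve,
    filtration_values,
    mean_network,
    merge_dendrogram,
    minimum_spanning_tree,
)
from topodmn.filtration import FiltrationProfile, write_dendrogram, write_profile

from helpers import (
    bfs_component_count,
    exhaustive_mst_weight,
    network_from,
    random_network,
)

TRIANGLE = network_from([[0, 0.1, 0.5], [0.1, 0, 0.2], [0.5, 0.2, 0]])


class TestMinimumSpanningTree:
    def test_three_node_example(self):
        tree = minimum_spanning_tree(TRIANGLE)
        assert {(i, j) for i, j, _ in tree.edges} == {(0, 1), (1, 2)}
        assert tree.total_weight == pytest.approx(0.3)

    def test_all_equal_weights(self):
        W = np.full((4, 4), 0.7)
        np.fill_diagonal(W, 0.0)
        tree = minimum_spanning_tree(network_from(W))
        assert tree.total_weight == pytest.approx(3 * 0.7)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            m = int(rng.integers(3, 7))
            net = random_network(m, rng)
            tree = minimum_spanning_tree(net)
            assert tree.total_weight == pytest.approx(
                exhaustive_mst_weight(net.weights), abs=1e-12
            )

    def test_tie_breaking_is_deterministic(self):
        W = np.full((5, 5), 0.5)
        np.fill_diagonal(W, 0.0)
        t1 = minimum_spanning_tree(network_from(W))
        t2 = minimum_spanning_tree(network_from(W))
        assert t1.edges == t2.edges
        # lexicographic tie-break: star rooted at node 0
        assert t1.edges == ((0, 1, 0.5), (0, 2, 0.5), (0, 3, 0.5), (0, 4, 0.5))

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            minimum_spanning_tree(network_from(np.zeros((1, 1))))


class TestFiltrationValues:
    def test_prepends_zero_and_sorts(self):
        tree = minimum_spanning_tree(TRIANGLE)
        np.testing.assert_allclose(filtration_values(tree), [0.0, 0.1, 0.2])

    def test_length_is_node_count(self, rng):
        net = random_network(26, rng)
        assert filtration_values(minimum_spanning_tree(net)).size == 26

    def test_duplicate_weights_kept_as_multiset(self):
        W = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.1, 0.9],
                [0.9, 0.1, 0.0, 0.3],
                [0.9, 0.9, 0.3, 0.0],
            ]
        )
        lams = filtration_values(minimum_spanning_tree(network_from(W)))
        np.testing.assert_allclose(lams, [0.0, 0.1, 0.1, 0.3])


class TestBetti0:
    def test_all_positive_weights_start_fully_disconnected(self, rng):
        net = random_network(26, rng)
        assert betti0_at(net, 0.0) == 26
        assert betti0_at(net, float(net.weights.max())) == 1

    def test_matches_bfs_component_count(self, rng):
        for _ in range(25):
            net = random_network(7, rng)
            lam = float(rng.uniform(0, 2))
            assert betti0_at(net, lam) == bfs_component_count(net.weights, lam)

    def test_chain_network_counts_down_one_by_one(self):
        # chain 0-1-2-3 with increasing rungs; long-range weights are larger
        W = np.array(
            [
                [0.0, 0.1, 0.8, 0.9],
                [0.1, 0.0, 0.2, 0.85],
                [0.8, 0.2, 0.0, 0.3],
                [0.9, 0.85, 0.3, 0.0],
            ]
        )
        prof = betti0_curve(network_from(W))
        np.testing.assert_array_equal(prof.betti0, [4, 3, 2, 1])
        np.testing.assert_allclose(prof.lambdas, [0.0, 0.1, 0.2, 0.3])

    def test_tied_mst_weights_step_by_two(self):
        W = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        prof = betti0_curve(network_from(W))
        np.testing.assert_array_equal(prof.betti0, [4, 2, 2, 1])

    def test_curve_is_nonincreasing_from_m_to_1(self, rng):
        for _ in range(100):
            m = int(rng.integers(3, 12))
            prof = betti0_curve(random_network(m, rng))
            assert prof.betti0[0] == m
            assert prof.betti0[-1] == 1
            assert np.all(np.diff(prof.betti0) <= 0)

    def test_drops_match_mst_weight_multiplicities(self, rng):
        net = random_network(10, rng)
        prof = betti0_curve(net)
        # at each lambda the curve has dropped by exactly the number of
        # MST edges with weight <= that lambda
        for i in range(prof.lambdas.size):
            n_edges = int(np.sum(prof.lambdas[1:] <= prof.lambdas[i] + 1e-15))
            assert prof.betti0[i] == net.n_nodes - n_edges


class TestMergeDendrogram:
    def test_three_node_merge_order(self):
        dendro = merge_dendrogram(TRIANGLE)
        assert len(dendro.events) == 2
        assert dendro.events[0].lam == pytest.approx(0.1)
        assert set(dendro.events[0].members_a + dendro.events[0].members_b) == {0, 1}
        assert dendro.events[1].lam == pytest.approx(0.2)
        final = dendro.events[1]
        assert set(final.members_a + final.members_b) == {0, 1, 2}

    def test_merge_heights_match_scipy_single_linkage(self, rng):
        for _ in range(10):
            net = random_network(9, rng)
            dendro = merge_dendrogram(net)
            Z = linkage(squareform(net.weights), method="single")
            np.testing.assert_allclose(
                [e.lam for e in dendro.events], Z[:, 2], atol=1e-12
            )

    def test_partitions_agree_with_betti0(self, rng):
        net = random_network(8, rng)
        dendro = merge_dendrogram(net)
        assert len(dendro.events) == 7
        for ev in dendro.events:
            # component count just below the merge is one higher than at it
            n_at = betti0_at(net, ev.lam)
            n_merges_at = sum(1 for e in dendro.events if e.lam <= ev.lam)
            assert n_at == net.n_nodes - n_merges_at


class TestInvariance:
    def test_monotone_weight_transform_preserves_topology(self, rng):
        net = random_network(12, rng)
        transformed = network_from(np.sqrt(net.weights))  # strictly increasing on [0,2]
        t1 = minimum_spanning_tree(net)
        t2 = minimum_spanning_tree(transformed)
        assert [(i, j) for i, j, _ in t1.edges] == [(i, j) for i, j, _ in t2.edges]
        np.testing.assert_array_equal(
            betti0_curve(net).betti0, betti0_curve(transformed).betti0
        )

    def test_distinct_merge_values_equal_distinct_mst_weights(self, rng):
        net = random_network(10, rng)
        tree = minimum_spanning_tree(net)
        dendro = merge_dendrogram(net)
        assert len({round(e.lam, 12) for e in dendro.events}) == len(
            {round(w, 12) for w in tree.weights}
        )


def test_profile_invariants_enforced():
    with pytest.raises(ValueError):
        FiltrationProfile(np.array([0.1, 0.2]), np.array([2, 1]))
    with pytest.raises(ValueError):
        FiltrationProfile(np.array([0.0, 0.2]), np.array([1, 2]))


def test_mean_network_is_elementwise_mean(rng):
    nets = [random_network(5, rng) for _ in range(3)]
    # give them identical labels
    from helpers import network_from as nf

    nets = [nf(n.weights) for n in nets]
    avg = mean_network(nets)
    np.testing.assert_allclose(
        avg.weights, np.mean([n.weights for n in nets], axis=0)
    )


def test_profile_and_dendrogram_exports(tmp_path, rng):
    net = random_network(5, rng)
    write_profile(betti0_curve(net), tmp_path / "prof.tsv")
    write_dendrogram(merge_dendrogram(net), tmp_path / "dendro.tsv")
    lines = (tmp_path / "prof.tsv").read_text().splitlines()
    assert lines[0] == "lambda\tbetti0"
    assert len(lines) == 6
    assert len((tmp_path / "dendro.tsv").read_text().splitlines()) == 5
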