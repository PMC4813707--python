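import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnpcp.pcp_clustering import (
    Dendrogram,
    DistanceMatrix,
    average_linkage,
    co_cluster,
    default_cut_height,
    heatmap_order,
    manhattan_matrix,
    to_newick,
)
from bnpcp.profiles import MigrationProfile


def profiles_from(matrix):
    return [MigrationProfile(f"P{i}", row, float(np.sum(row)) or 1.0) for i, row in enumerate(matrix)]


def brute_force_upgma(d):
    """Independent UPGMA oracle: recompute every inter-cluster mean from the
    original matrix at every step; same tie rule (lowest index pair)."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            mean = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            key = (mean, (a, b))
            if best is None or key < best[0]:
                best = (key, a, b)
        (mean, _), a, b = best
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, mean))
        nxt += 1
    return merges


def random_distance_matrix(rng, n, integer=False):
    if integer:
        upper = rng.integers(1, 6, size=(n, n)).astype(float)
    else:
        upper = rng.random((n, n))
    d = np.triu(upper, 1)
    d = d + d.T
    return d


class TestManhattanMatrix:
    def test_closed_form(self):
        profs = profiles_from(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert manhattan_matrix(profs).d[0, 1] == 2.0

    def test_identical_profiles_distance_zero(self):
        profs = profiles_from(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert manhattan_matrix(profs).d[0, 1] == 0.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(123)
        mat = rng.random((5, 6))
        profs = profiles_from(mat)
        d = manhattan_matrix(profs).d
        for i in range(5):
            for j in range(5):
                assert d[i, j] == pytest.approx(sum(abs(mat[i, f] - mat[j, f]) for f in range(6)))

    def test_length_mismatch_is_error(self):
        profs = [
            MigrationProfile("A", np.array([1.0, 0.0]), 1.0),
            MigrationProfile("B", np.array([1.0, 0.0, 0.0]), 1.0),
        ]
        with pytest.raises(ValueError):
            manhattan_matrix(profs)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.random((4, 5))
        d = manhattan_matrix(profiles_from(mat)).d
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0)
        for i, j, k in itertools.permutations(range(4), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestAverageLinkage:
    def test_three_leaf_hand_computed(self):
        d = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        tree = average_linkage(DistanceMatrix(["A", "B", "C"], d))
        assert tree.merges[0] == (0, 1, 1.0)
        a, b, h = tree.merges[1]
        assert {a, b} == {2, 3}
        assert h == pytest.approx(10.0)

    def test_two_leaves(self):
        d = np.array([[0.0, 4.0], [4.0, 0.0]])
        tree = average_linkage(DistanceMatrix(["A", "B"], d))
        assert tree.merges == [(0, 1, 4.0)]

    def test_four_leaf_matches_oracle(self):
        rng = np.random.default_rng(77)
        d = random_distance_matrix(rng, 4)
        tree = average_linkage(DistanceMatrix([f"P{i}" for i in range(4)], d))
        oracle = brute_force_upgma(d)
        for got, want in zip(tree.merges, oracle):
            assert got[:2] == want[:2]
            assert got[2] == pytest.approx(want[2])

    @pytest.mark.parametrize("integer", [False, True], ids=["real", "tied-integer"])
    def test_oracle_agreement_100_seeds(self, integer):
        rng = np.random.default_rng(20_000 + integer)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            d = random_distance_matrix(rng, n, integer=integer)
            tree = average_linkage(DistanceMatrix([f"P{i}" for i in range(n)], d))
            oracle = brute_force_upgma(d)
            for got, want in zip(tree.merges, oracle):
                assert got[:2] == want[:2]
                assert got[2] == pytest.approx(want[2])


class TestCoCluster:
    def _tree(self):
        d = np.array(
            [
                [0.0, 1.0, 5.0, 9.0],
                [1.0, 0.0, 5.0, 9.0],
                [5.0, 5.0, 0.0, 9.0],
                [9.0, 9.0, 9.0, 0.0],
            ]
        )
        return average_linkage(DistanceMatrix(["A", "B", "C", "D"], d))

    def test_height_zero_is_singleton(self):
        assert co_cluster(self._tree(), "A", 0.0) == {"A"}

    def test_root_cut_is_everything(self):
        tree = self._tree()
        top = max(h for _, _, h in tree.merges)
        assert co_cluster(tree, "A", top) == {"A", "B", "C", "D"}

    def test_intermediate_cut(self):
        assert co_cluster(self._tree(), "A", 5.0) == {"A", "B", "C"}

    def test_unknown_bait_is_error(self):
        with pytest.raises(ValueError):
            co_cluster(self._tree(), "Z", 1.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_height(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        d = random_distance_matrix(rng, n)
        tree = average_linkage(DistanceMatrix([f"P{i}" for i in range(n)], d))
        heights = sorted([0.0] + [h for _, _, h in tree.merges])
        prev: set = set()
        for h in heights:
            members = co_cluster(tree, "P0", h)
            assert prev <= members
            prev = members


class TestHeatmapOrder:
    def test_two_proteins(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        dist = DistanceMatrix(["A", "B"], d)
        ids, mat = heatmap_order(average_linkage(dist), dist)
        assert ids == ["A", "B"]
        np.testing.assert_array_equal(mat, d)

    def test_reordered_is_permutation(self):
        rng = np.random.default_rng(3)
        d = random_distance_matrix(rng, 6)
        dist = DistanceMatrix([f"P{i}" for i in range(6)], d)
        ids, mat = heatmap_order(average_linkage(dist), dist)
        assert sorted(ids) == sorted(dist.ids)
        assert sorted(np.round(mat.ravel(), 12)) == sorted(np.round(d.ravel(), 12))

    def test_id_mismatch_is_error(self):
        d = np.zeros((2, 2))
        dist = DistanceMatrix(["A", "B"], d)
        tree = Dendrogram(ids=["A", "C"], merges=[(0, 1, 0.0)])
        with pytest.raises(ValueError):
            heatmap_order(tree, dist)

    def test_leaf_order_beats_random_order_on_synthetic_fixture(self):
        # adjacent-leaf mean distance under the dendrogram order should beat
        # the average over random orders (fixed-seed Monte Carlo)
        from bnpcp.profiles import build_profiles
        from bnpcp.synthetic_data import default_truth, simulate_table

        truth = default_truth(seed=5, noise_cv=0.1, dropout_rate=0.0)
        profs = [p for p in build_profiles(simulate_table(truth, 1)) if not p.is_zero()]
        dist = manhattan_matrix(profs)
        tree = average_linkage(dist)
        ids, mat = heatmap_order(tree, dist)

        def adjacent_mean(m):
            return np.mean([m[i, i + 1] for i in range(m.shape[0] - 1)])

        ordered_score = adjacent_mean(mat)
        rng = np.random.default_rng(0)
        random_scores = []
        for _ in range(200):
            perm = rng.permutation(len(ids))
            random_scores.append(adjacent_mean(dist.d[np.ix_(perm, perm)]))
        assert ordered_score < np.mean(random_scores)


class TestDefaultCutAndNewick:
    def test_default_cut_reaches_min_members(self):
        rng = np.random.default_rng(8)
        d = random_distance_matrix(rng, 6)
        tree = average_linkage(DistanceMatrix([f"P{i}" for i in range(6)], d))
        h = default_cut_height(tree, "P0", min_members=3)
        assert len(co_cluster(tree, "P0", h)) >= 3

    def test_newick_parses_with_dendropy(self):
        import dendropy

        d = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        tree = average_linkage(DistanceMatrix(["A", "B", "C"], d))
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {"A", "B", "C"}
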