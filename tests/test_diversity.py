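from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from clovermark.diversity import (
    DistanceMatrix,
    average_distance,
    diversity_tree,
    marker_distance_matrix,
    pair_similarity,
    upgma,
)
from clovermark.simulate import MarkerModel, SimConfig, simulate_band_matrix

from tests.conftest import band_matrix_from_profiles
from tests.oracles import cophenetic_matrix


def random_distance_matrix(rng, n, labels=None):
    raw = rng.random((n, n))
    d = (raw + raw.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = labels or tuple(f"v{i:02d}" for i in range(n))
    return DistanceMatrix(labels, d)


band_sets = st.sets(st.sampled_from("abcdefgh"), max_size=8)


class TestPairSimilarity:
    def test_identical_sets(self):
        assert pair_similarity({"a", "b"}, {"a", "b"}, "jaccard") == 1.0
        assert pair_similarity({"a", "b"}, {"a", "b"}, "dice") == 1.0

    def test_disjoint_sets(self):
        assert pair_similarity({"a"}, {"b"}, "jaccard") == 0.0
        assert pair_similarity({"a"}, {"b"}, "dice") == 0.0

    def test_formula_values(self):
        x, y = {"a", "b", "c"}, {"a", "d"}
        assert pair_similarity(x, y, "jaccard") == pytest.approx(0.25)
        assert pair_similarity(x, y, "dice") == pytest.approx(0.4)

    def test_both_empty_indistinguishable(self):
        assert pair_similarity(set(), set(), "jaccard") == 1.0
        assert pair_similarity(set(), {"a"}, "jaccard") == 0.0

    @given(x=band_sets, y=band_sets)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_dice_bounds_jaccard(self, x, y):
        j = pair_similarity(x, y, "jaccard")
        d = pair_similarity(x, y, "dice")
        assert d >= j - 1e-12
        if j in (0.0, 1.0):
            assert d == pytest.approx(j)
        else:
            assert d > j


class TestMarkerDistances:
    def test_identical_profiles_zero(self):
        bm = band_matrix_from_profiles({"v1": {"a"}, "v2": {"a"}})
        dm = marker_distance_matrix(bm, "m1")
        assert dm.d[0, 1] == 0.0

    def test_disjoint_profiles_one(self):
        bm = band_matrix_from_profiles({"v1": {"a"}, "v2": {"b"}})
        assert marker_distance_matrix(bm, "m1").d[0, 1] == 1.0

    def test_three_variety_worked_example(self, three_variety_bands):
        dm = marker_distance_matrix(three_variety_bands, "m1", "jaccard")
        assert dm.d[0, 1] == pytest.approx(0.5)
        assert dm.d[0, 2] == 1.0
        assert dm.d[1, 2] == 1.0

    def test_unknown_marker(self, three_variety_bands):
        with pytest.raises(KeyError):
            marker_distance_matrix(three_variety_bands, "nope")

    def test_both_indices_order_pairs_identically(self, rng):
        profiles = {
            f"v{i}": set(rng.choice(list("abcdef"), size=rng.integers(1, 5), replace=False))
            for i in range(6)
        }
        bm = band_matrix_from_profiles(profiles)
        dj = marker_distance_matrix(bm, "m1", "jaccard").d
        dd = marker_distance_matrix(bm, "m1", "dice").d
        iu = np.triu_indices(6, 1)
        assert (np.argsort(dj[iu], kind="stable") == np.argsort(dd[iu], kind="stable")).all()


class TestAverageDistance:
    def test_self_average_identity(self, rng):
        dm = random_distance_matrix(rng, 4)
        avg = average_distance([dm, dm])
        assert np.allclose(avg.d, dm.d)

    def test_all_zero_and_all_one(self):
        labels = ("a", "b")
        z = DistanceMatrix(labels, np.zeros((2, 2)))
        o = DistanceMatrix(labels, np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert average_distance([z, o]).d[0, 1] == 0.5

    def test_matches_recompute_and_permutation_invariant(self, rng):
        ms = [random_distance_matrix(rng, 5, labels=tuple("abcde")) for _ in range(3)]
        avg = average_distance(ms)
        expected = (ms[0].d + ms[1].d + ms[2].d) / 3
        assert np.allclose(avg.d, expected)
        assert np.allclose(average_distance(ms[::-1]).d, avg.d)

    def test_label_mismatch_rejected(self, rng):
        a = random_distance_matrix(rng, 3, labels=("a", "b", "c"))
        b = random_distance_matrix(rng, 3, labels=("a", "b", "d"))
        with pytest.raises(ValueError, match="labels"):
            average_distance([a, b])


class TestUpgma:
    def test_worked_three_leaf_example(self):
        dm = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = upgma(dm)
        assert tree.height == 2.0
        ab = tree.children[0]
        assert ab.leaf_labels() == {"A", "B"}
        assert ab.height == 1.0

    def test_two_leaves(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        tree = upgma(dm)
        assert tree.height == 0.5

    def test_ultrametric_leaf_depths_equal(self, rng):
        for _ in range(20):
            dm = random_distance_matrix(rng, int(rng.integers(3, 9)))
            tree = upgma(dm)

            def depths(node, acc=0.0):
                if node.is_leaf:
                    return [acc]
                return [
                    d
                    for c in node.children
                    for d in depths(c, acc + node.height - c.height)
                ]

            ds = depths(tree)
            assert max(ds) - min(ds) < 1e-9

    def test_agrees_with_scipy_average_linkage(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 8))
            dm = random_distance_matrix(rng, n)
            tree = upgma(dm)
            ours = cophenetic_matrix(tree, dm.labels)
            theirs = squareform(cophenet(linkage(squareform(dm.d), "average")))
            # scipy cophenetic distances are the merge heights (= 2x ours/2)
            assert np.allclose(ours, theirs, atol=1e-9)

    def test_tie_break_is_order_invariant(self):
        d = np.array(
            [[0.0, 0.4, 0.4, 0.8],
             [0.4, 0.0, 0.4, 0.8],
             [0.4, 0.4, 0.0, 0.8],
             [0.8, 0.8, 0.8, 0.0]]
        )
        t1 = upgma(DistanceMatrix(("b", "a", "c", "d"), d))
        # permute rows: same labels in different order must give the same tree
        perm = [1, 0, 2, 3]
        t2 = upgma(DistanceMatrix(("a", "b", "c", "d"), d[np.ix_(perm, perm)]))
        assert t1.cophenetic() == t2.cophenetic()
        first = t1.children[0] if not t1.children[0].is_leaf else t1.children[1]
        # lexicographic tie-break merges (a, b) first
        assert {"a", "b"}.issubset(first.leaf_labels())


class TestClusterRecovery:
    def test_two_simulated_groups_split_at_root(self):
        n_sims = 200
        hits = 0
        group1 = {f"variety_{i + 1:03d}" for i in range(6)}
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            # strong separation: group-specific bands at high frequency
            profiles = {}
            for i in range(12):
                group = 0 if i < 6 else 1
                bands = set()
                for b in range(8):
                    f = 0.97 if (b < 4) == (group == 0) else 0.03
                    if rng.random() < f:
                        bands.add(f"b{b}")
                profiles[f"variety_{i + 1:03d}"] = bands
            bm = band_matrix_from_profiles(profiles)
            _, tree = diversity_tree(bm, "jaccard")
            sides = {child.leaf_labels() for child in tree.children}
            if group1 in sides:
                hits += 1
        assert hits / n_sims >= 0.95

    def test_simulated_matrix_round_trip(self):
        cfg = SimConfig(
            seed=5,
            n_varieties=8,
            markers=(MarkerModel((0.6, 0.4)), MarkerModel((0.5,), 0.7)),
        )
        bm, _ = simulate_band_matrix(cfg)
        avg, tree = diversity_tree(bm, "dice")
        assert tree.leaf_labels() == set(bm.varieties)
        assert avg.d.max() <= 1.0 + 1e-12
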