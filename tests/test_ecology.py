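"""Dissimilarities, NMDS, and PERMANOVA against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from skbio import DistanceMatrix

from glycoferm.ecology import (
    bray_curtis,
    gower,
    nmds,
    pairwise_distances,
    permanova,
    weighted_unifrac,
)
from glycoferm.io import parse_newick
from glycoferm.simulate import random_tree


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def unifrac_bruteforce(x: dict, y: dict, tree, normalized=False) -> float:
    """Explicit per-branch descendant enumeration (quadratic, no sharing)."""
    raw = 0.0
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        a = sum(x.get(t, 0.0) for t in below)
        b = sum(y.get(t, 0.0) for t in below)
        raw += (node.length or 0.0) * abs(a - b)
    if not normalized:
        return raw
    denom = 0.0
    for tip in tree.tips():
        d, node = 0.0, tip
        while not node.is_root():
            d += node.length or 0.0
            node = node.parent
        denom += d * (x.get(tip.name, 0.0) + y.get(tip.name, 0.0))
    return raw / denom if denom else 0.0


def permanova_f_oracle(D: np.ndarray, labels: np.ndarray) -> float:
    """Direct pseudo-F from the sums-of-squares definition."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    ss_t = sum(D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(D[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def random_composition(rng, taxa):
    v = rng.random(len(taxa))
    v /= v.sum()
    return dict(zip(taxa, v))


# ---------------------------------------------------------------------------
# Bray-Curtis / Gower
# ---------------------------------------------------------------------------

class TestBrayCurtis:
    def test_identity(self):
        x = np.array([0.2, 0.3, 0.5])
        assert bray_curtis(x, x) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_hand_computed(self):
        assert bray_curtis([1, 0, 3], [0, 2, 2]) == pytest.approx(0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([-1, 1], [1, 1])

    def test_both_zero_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="glycoferm"):
            assert bray_curtis([0, 0], [0, 0]) == 0.0
        assert "all-zero" in caplog.text


class TestGower:
    def test_identity(self):
        assert gower([1, 2], [1, 2], [5, 5]) == 0.0

    def test_full_range_is_one(self):
        assert gower([0], [10], [10]) == 1.0

    def test_hand_computed(self):
        assert gower([5, 1], [0, 0], [10, 2]) == pytest.approx(0.5)

    def test_zero_range_excluded(self, caplog):
        with caplog.at_level("WARNING", logger="glycoferm"):
            d = gower([1, 0], [1, 1], [0, 2])
        assert d == pytest.approx(0.5)
        assert "zero-range" in caplog.text

    def test_all_zero_range_is_error(self):
        with pytest.raises(ValueError):
            gower([1], [2], [0])


# ---------------------------------------------------------------------------
# Weighted UniFrac
# ---------------------------------------------------------------------------

class TestWeightedUnifrac:
    def test_identity_both_forms(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        x = {"A": 0.5, "B": 0.3, "C": 0.2}
        assert weighted_unifrac(x, x, tree) == 0.0
        assert weighted_unifrac(x, x, tree, normalized=True) == 0.0

    def test_two_leaf_hand_sum(self):
        tree = parse_newick("(A:1,B:1);")
        x, y = {"A": 1.0}, {"B": 1.0}
        assert weighted_unifrac(x, y, tree) == pytest.approx(2.0)
        assert weighted_unifrac(x, y, tree, normalized=True) == pytest.approx(1.0)

    def test_missing_taxon_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="missing"):
            weighted_unifrac({"Z": 1.0}, {"A": 1.0}, tree)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"L{i}" for i in range(8)]
        tree = random_tree(taxa, rng)
        x = random_composition(rng, taxa)
        y = random_composition(rng, taxa)
        for normalized in (False, True):
            fast = weighted_unifrac(x, y, tree, normalized=normalized)
            slow = unifrac_bruteforce(x, y, tree, normalized=normalized)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_matches_skbio(self):
        """Independent cross-check against scikit-bio's implementation."""
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(7)
        taxa = [f"L{i}" for i in range(10)]
        tree = random_tree(taxa, rng)
        counts = rng.integers(1, 1000, size=(4, 10))  # skbio expects counts
        rel = counts / counts.sum(axis=1, keepdims=True)
        ours = np.zeros((4, 4))
        rows = [dict(zip(taxa, c)) for c in rel]
        for i in range(4):
            for j in range(i + 1, 4):
                ours[i, j] = ours[j, i] = weighted_unifrac(rows[i], rows[j], tree)
        theirs = beta_diversity("weighted_unifrac", counts, taxa=taxa, tree=tree,
                                validate=True)
        assert np.abs(ours - theirs.data).max() < 1e-10


class TestDistanceProperties:
    @pytest.mark.parametrize("metric", ["braycurtis", "euclidean", "gower"])
    def test_metric_axioms_on_random_tables(self, metric):
        rng = np.random.default_rng(11)
        table = pd.DataFrame(rng.random((6, 5)),
                             index=[f"s{i}" for i in range(6)])
        dm = pairwise_distances(table, metric=metric)
        assert np.allclose(np.diag(dm.data), 0.0)
        assert np.abs(dm.data - dm.data.T).max() < 1e-12
        assert (dm.data >= 0).all()


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

class TestNMDS:
    def test_exact_planar_configuration_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.random((8, 2)) * 4
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        result = nmds(DistanceMatrix(D, ids=[str(i) for i in range(8)]), seed=1)
        assert result.stress < 0.01

    def test_equilateral_triangle(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        result = nmds(DistanceMatrix(D, ids=list("abc")), seed=0)
        assert result.stress < 0.01

    def test_planted_clusters_preserve_ranks(self):
        # two planted clusters: within-cluster distances ~0.1, between ~1.0,
        # drawn from an actual 2-D configuration so a faithful embedding exists
        # (pure two-level distances trigger the classic NMDS cluster-collapse
        # degeneracy, under which within-cluster ranks are not recoverable)
        rng = np.random.default_rng(5)
        n = 10
        centers = np.array([[0.0, 0.0], [1.0, 0.0]])
        pts = np.vstack([c + rng.normal(0, 0.05, size=(5, 2)) for c in centers])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(D, ids=[str(i) for i in range(n)])
        result = nmds(dm, seed=2)
        coords = result.coordinates.to_numpy()
        out = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        iu = np.triu_indices(n, 1)
        rho = spearmanr(D[iu], out[iu]).statistic
        assert rho >= 0.9

    def test_coordinates_centered(self):
        rng = np.random.default_rng(9)
        pts = rng.random((6, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        result = nmds(DistanceMatrix(D, ids=list("abcdef")), seed=0)
        assert np.abs(result.coordinates.mean(axis=0).to_numpy()).max() < 1e-9

    def test_stress_monotone_within_restart(self):
        rng = np.random.default_rng(13)
        table = rng.random((9, 4))
        dm = pairwise_distances(pd.DataFrame(table), metric="braycurtis")
        result = nmds(dm, seed=4)
        h = result.stress_history
        assert all(h[i + 1] <= h[i] + 1e-12 for i in range(len(h) - 1))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(17)
        table = pd.DataFrame(rng.random((7, 4)))
        dm = pairwise_distances(table, metric="braycurtis")
        r1 = nmds(dm, seed=6)
        r2 = nmds(dm, seed=6)
        assert np.array_equal(r1.coordinates.to_numpy(), r2.coordinates.to_numpy())

    def test_nonfinite_rejected(self):
        D = np.array([[0.0, np.inf], [np.inf, 0.0]])
        dm = DistanceMatrix.__new__(DistanceMatrix)  # bypass skbio validation
        with pytest.raises(Exception):
            nmds(DistanceMatrix(np.nan_to_num(D), ids=list("ab")), dims=2)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

class TestPermanova:
    def _random_dm(self, rng, n):
        pts = rng.random((n, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return DistanceMatrix(D, ids=[f"s{i}" for i in range(n)])

    def test_pseudo_f_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        dm = self._random_dm(rng, 12)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        res = permanova(dm, labels, n_perm=99, seed=0)
        assert res.pseudo_f == pytest.approx(permanova_f_oracle(dm.data, labels),
                                             abs=1e-10)

    def test_pseudo_f_matches_skbio(self):
        """Independent cross-check: skbio computes the same pseudo-F."""
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(8)
        dm = self._random_dm(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, labels, n_perm=99, seed=0)
        theirs = sk_permanova(dm, grouping=labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_exhaustive_enumeration_exact_n4(self):
        rng = np.random.default_rng(4)
        dm = self._random_dm(rng, 4)
        labels = ["a", "a", "b", "b"]
        res = permanova(dm, labels, n_perm=999, seed=0)
        assert res.method == "exhaustive"
        # oracle: enumerate all 4! relabelings directly
        f_obs = permanova_f_oracle(dm.data, np.array([0, 0, 1, 1]))
        fs = [permanova_f_oracle(dm.data[np.ix_(p, p)], np.array([0, 0, 1, 1]))
              for p in itertools.permutations(range(4))]
        expected_p = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        assert res.p_value == pytest.approx(expected_p, abs=1e-12)

    def test_constant_matrix_f_is_one(self):
        D = np.ones((6, 6)) - np.eye(6)
        dm = DistanceMatrix(D, ids=[f"s{i}" for i in range(6)])
        res = permanova(dm, [0, 0, 0, 1, 1, 1], n_perm=99, seed=0)
        assert res.pseudo_f == pytest.approx(1.0)
        assert res.constant_matrix

    def test_label_reordering_invariance_exhaustive(self):
        rng = np.random.default_rng(6)
        dm = self._random_dm(rng, 5)
        labels = np.array([0, 0, 1, 1, 1])
        res1 = permanova(dm, labels, n_perm=999, seed=0)
        order = [3, 1, 4, 0, 2]
        D2 = dm.data[np.ix_(order, order)]
        dm2 = DistanceMatrix(D2, ids=[f"s{i}" for i in order])
        res2 = permanova(dm2, labels[order], n_perm=999, seed=0)
        assert res1.p_value == pytest.approx(res2.p_value, abs=1e-12)
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f, abs=1e-10)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(1)
        dm = self._random_dm(rng, 4)
        with pytest.raises(ValueError):
            permanova(dm, [0, 0, 0, 0], n_perm=99)
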