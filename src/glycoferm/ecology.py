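"""Community dissimilarities, NMDS ordination, and PERMANOVA.

These are implemented from first principles (the statistics themselves
are the contract) rather than delegated: weighted UniFrac by a single
postorder traversal accumulating descendant abundances per branch, NMDS
by alternating monotone (isotonic) regression and Guttman-transform
majorization of Kruskal stress-1, and PERMANOVA by the pseudo-F
decomposition of squared dissimilarities with label permutation
(exhaustive enumeration when the group sizes allow).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger("glycoferm")


# ---------------------------------------------------------------------------
# Pairwise dissimilarities
# ---------------------------------------------------------------------------

def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    denom = float((x + y).sum())
    if denom == 0.0:
        logger.warning("Bray-Curtis of two all-zero vectors; returning 0")
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def gower(x: np.ndarray, y: np.ndarray, ranges: np.ndarray) -> float:
    """Gower dissimilarity: mean over features of |x-y| / range.

    Features with zero range are excluded with a warning; an all-zero
    range vector is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranges = np.asarray(ranges, dtype=float)
    usable = ranges > 0
    if not usable.any():
        raise ValueError("all features have zero range")
    if not usable.all():
        logger.warning("excluding %d zero-range feature(s) from Gower distance",
                       int((~usable).sum()))
    return float(np.mean(np.abs(x[usable] - y[usable]) / ranges[usable]))


def weighted_unifrac(x, y, tree: TreeNode, normalized: bool = False) -> float:
    """Weighted UniFrac between two relative-abundance vectors on a tree.

    Raw form: sum over branches of branch_length * |A_b - B_b| where A_b,
    B_b are the summed relative abundances of the leaves below the
    branch. Normalized form divides by sum over leaves of
    root_distance_j * (A_j + B_j).

    ``x`` and ``y`` may be dicts or pandas Series keyed by leaf name.
    """
    x = dict(x)
    y = dict(y)
    leaf_names = {t.name for t in tree.tips()}
    for taxon in itertools.chain(x, y):
        if taxon not in leaf_names:
            raise ValueError(f"taxon {taxon!r} missing from tree")

    raw = 0.0
    denom = 0.0
    # postorder accumulation of descendant abundance sums
    sums: dict[int, tuple[float, float]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            a, b = float(x.get(node.name, 0.0)), float(y.get(node.name, 0.0))
        else:
            a = sum(sums[id(c)][0] for c in node.children)
            b = sum(sums[id(c)][1] for c in node.children)
        sums[id(node)] = (a, b)
        length = node.length or 0.0
        if length < 0:
            raise ValueError("negative branch length")
        if not node.is_root():
            raw += length * abs(a - b)
    if not normalized:
        return raw
    for tip in tree.tips():
        d = 0.0
        node = tip
        while not node.is_root():
            d += node.length or 0.0
            node = node.parent
        denom += d * (float(x.get(tip.name, 0.0)) + float(y.get(tip.name, 0.0)))
    if denom == 0.0:
        return 0.0
    return raw / denom


_METRICS = {"braycurtis": bray_curtis}


def pairwise_distances(table: pd.DataFrame, metric: str = "braycurtis",
                       tree: TreeNode | None = None,
                       normalized_unifrac: bool = False) -> DistanceMatrix:
    """Samples x samples dissimilarity matrix from a samples x features table."""
    ids = list(table.index)
    n = len(ids)
    mat = np.zeros((n, n))
    X = table.to_numpy(dtype=float)
    if metric == "euclidean":
        mat = squareform(pdist(X, metric="euclidean"))
    elif metric == "braycurtis" and not (X.sum(axis=1) == 0).any():
        # vectorized route; identical to bray_curtis pair by pair (tested)
        mat = squareform(np.nan_to_num(pdist(X, metric="braycurtis")))
    elif metric == "gower":
        ranges = X.max(axis=0) - X.min(axis=0)
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = gower(X[i], X[j], ranges)
    elif metric == "weighted_unifrac":
        if tree is None:
            raise ValueError("weighted UniFrac needs a tree")
        series = [table.iloc[i].to_dict() for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = weighted_unifrac(
                    series[i], series[j], tree, normalized=normalized_unifrac)
    elif metric in _METRICS:
        fn = _METRICS[metric]
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = fn(X[i], X[j])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(mat, ids=ids)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Best-stress NMDS configuration over random restarts."""

    coordinates: pd.DataFrame  # samples x dims, centered at the origin
    stress: float  # Kruskal stress-1
    converged: bool
    n_restarts: int
    seed: int
    stress_history: list[float] | None = None


def _kruskal_stress(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d ** 2).sum())
    if denom == 0.0:
        return 0.0
    return math.sqrt(float(((d - dhat) ** 2).sum()) / denom)


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _nmds_single(D: np.ndarray, dims: int, X0: np.ndarray, max_iter: int,
                 tol: float) -> tuple[np.ndarray, float, bool, list[float]]:
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    delta = D[iu]
    # monotone regression bookkeeping, fixed across iterations: sort pairs by
    # dissimilarity and pre-pool tied dissimilarities (pooled-ties treatment)
    order = np.argsort(delta, kind="stable")
    delta_sorted = delta[order]
    blocks = np.concatenate([[0], np.cumsum(np.diff(delta_sorted) > 0)])
    counts = np.bincount(blocks).astype(float)
    inverse_order = np.empty_like(order)
    inverse_order[order] = np.arange(order.size)
    X = X0.copy()
    history: list[float] = []
    best_X, best_stress = X, np.inf
    converged = False
    for _ in range(max_iter):
        d = squareform(np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)),
                       checks=False)
        block_means = np.bincount(blocks, weights=d[order]) / counts
        fitted = isotonic_regression(block_means, weights=counts, increasing=True).x
        dhat = fitted[blocks][inverse_order]
        stress = _kruskal_stress(d, dhat)
        if stress >= best_stress - 1e-15:
            # keep the monotone-descent guarantee: stop on non-improvement
            if best_stress - stress < tol:
                converged = True
            break
        best_stress, best_X = stress, X.copy()
        history.append(stress)
        if stress == 0.0:
            converged = True
            break
        # Guttman transform toward the disparities
        Dhat = squareform(dhat, checks=False)
        Dfull = squareform(d, checks=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(Dfull > 0, Dhat / np.where(Dfull > 0, Dfull, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
    return best_X, best_stress, converged, history


def nmds(dm: DistanceMatrix, dims: int = 2, n_restarts: int = 4, seed: int = 0,
         max_iter: int = 300, tol: float = 1e-7) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Each restart alternates isotonic regression of configuration
    distances on the input dissimilarities with a Guttman-transform
    update; the first restart is initialized from classical metric
    scaling, the rest at random. The best-stress configuration is
    returned, centered at the origin. Stress is non-increasing across
    the recorded iterations of each restart by construction.
    """
    D = dm.data
    n = D.shape[0]
    if dims < 2:
        raise ValueError("dims must be >= 2")
    if n < dims + 1:
        raise ValueError("need at least dims + 1 samples")
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, bool, list[float]] | None = None
    for r in range(n_restarts):
        if r == 0:
            X0 = _classical_mds(D, dims)
            if not np.isfinite(X0).all() or np.allclose(X0, 0):
                X0 = rng.normal(size=(n, dims))
        else:
            X0 = rng.normal(size=(n, dims))
        result = _nmds_single(D, dims, X0, max_iter, tol)
        if best is None or result[1] < best[1]:
            best = result
    X, stress, converged, history = best
    X = X - X.mean(axis=0, keepdims=True)
    coords = pd.DataFrame(X, index=list(dm.ids),
                          columns=[f"NMDS{i + 1}" for i in range(dims)])
    return OrdinationResult(coordinates=coords, stress=stress, converged=converged,
                            n_restarts=n_restarts, seed=seed, stress_history=history)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str  # "exhaustive" or "sampled"
    constant_matrix: bool = False


def _permanova_ss(D2: np.ndarray, labels: np.ndarray, uniq: np.ndarray
                  ) -> tuple[float, float]:
    n = D2.shape[0]
    ss_total = float(D2[np.triu_indices(n, k=1)].sum()) / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += float(sub[np.triu_indices(idx.size, k=1)].sum()) / idx.size
    return ss_total, ss_within


def _pseudo_f(D2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    n = D2.shape[0]
    a = uniq.size
    ss_total, ss_within = _permanova_ss(D2, labels, uniq)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
              ) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = (SS_A/(a-1)) / (SS_W/(N-a)) with SS_T computed from all
    squared pairwise dissimilarities and SS_W from within-group pairs.
    The p-value permutes group labels; when N! <= n_perm the full
    permutation distribution is enumerated and the p-value is exact,
    otherwise ``n_perm`` random permutations are drawn and the +1
    correction applied (the p-value is never 0).
    """
    labels = np.asarray(pd.Categorical(list(groups)).codes)
    if labels.size != dm.shape[0]:
        raise ValueError("groups length must match distance matrix")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    D = dm.data
    D2 = D ** 2
    n = D.shape[0]
    off = D[np.triu_indices(n, k=1)]
    constant = bool(np.allclose(off, off[0]))
    if constant:
        logger.warning("constant distance matrix: pseudo-F carries no information")
    f_obs = _pseudo_f(D2, labels, uniq)

    if math.factorial(n) <= n_perm:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            f_p = _pseudo_f(D2, labels[list(perm)], uniq)
            count += f_p >= f_obs - 1e-12
            total += 1
        return PermanovaResult(float(f_obs), count / total, total, "exhaustive",
                               constant)

    rng = np.random.default_rng(seed)
    # vectorized permutation engine: SS_W via group indicator contractions
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    L = labels[perms]  # (n_perm, n)
    triu = np.triu_indices(n, k=1)
    ss_total = float(D2[triu].sum()) / n
    ss_within = np.zeros(n_perm)
    for g in uniq:
        M = (L == g).astype(float)  # (n_perm, n)
        n_g = int((labels == g).sum())
        # sum over ordered within-group pairs = M D2 M^T diagonal
        quad = np.einsum("pi,ij,pj->p", M, D2, M)
        ss_within += quad / (2.0 * n_g)
    a = uniq.size
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_among / (a - 1)) / (ss_within / (n - a))
    f_perm = np.where(ss_within <= 0, np.where(ss_among > 0, np.inf, 0.0), f_perm)
    p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_perm)
    return PermanovaResult(float(f_obs), p, n_perm, "sampled", constant)
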