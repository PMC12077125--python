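"""Glycomic profile normalization, phyloglycomic clustering, and
structure-based classification of novel fibers.

Raw glycosidic-linkage peak areas are not directly comparable because
linkages ionize at different rates (terminal linkages overrepresented),
so per parent sugar the raw areas are rescaled to sum to that sugar's
monosaccharide abundance. Fibers are then clustered on Euclidean
distances between compositions into "phyloglycomic groups", and a novel
fiber is assigned to the group whose members it is closest to on average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import braycurtis as _bc, euclidean as _euc, pdist

from glycoferm.io import CLOSURE_TOL, GlycanProfile

logger = logging.getLogger("glycoferm")


def normalize_linkages(p: GlycanProfile) -> GlycanProfile:
    """Rescale raw linkage areas per parent sugar to the mono composition.

    For each monosaccharide ``m``, the linkages annotated with parent
    ``m`` are rescaled so their normalized abundances sum exactly to
    ``mono_abundance[m]``. A parent with nonzero abundance but zero total
    raw area gets its whole mass as a synthetic ``unannotated-<m>``
    feature (the measured linkage list is not exhaustive). Mutates and
    returns ``p`` with ``linkage_norm`` filled.
    """
    for link, area in p.linkage_raw.items():
        if area < 0:
            raise ValueError(f"{p.fiber_id}: negative raw area for {link!r}")
        if p.linkage_parent.get(link) not in p.mono_abundance:
            raise ValueError(f"{p.fiber_id}: linkage {link!r} lacks a known parent")
    norm: dict[str, float] = {}
    for m, share in p.mono_abundance.items():
        members = [l for l, par in p.linkage_parent.items()
                   if par == m and l in p.linkage_raw]
        total = sum(p.linkage_raw[l] for l in members)
        if total > 0:
            for l in members:
                norm[l] = p.linkage_raw[l] / total * share
        elif share > 0:
            logger.warning("%s: no annotated linkages for %s; mass kept as unannotated",
                           p.fiber_id, m)
            norm[f"unannotated-{m}"] = share
    p.linkage_norm = norm
    return p


def build_profile_matrix(fibers: list[GlycanProfile], layer: str = "mono") -> pd.DataFrame:
    """Fibers x features matrix for one glycomic layer; rows sum to 1.

    The feature set is the union across fibers, absent features filled
    with zero.
    """
    rows: dict[str, dict[str, float]] = {}
    for p in fibers:
        if layer == "mono":
            rows[p.fiber_id] = dict(p.mono_abundance)
        elif layer == "linkage":
            if p.linkage_norm is None:
                raise ValueError(
                    f"{p.fiber_id}: linkage layer requested before normalize_linkages"
                )
            rows[p.fiber_id] = dict(p.linkage_norm)
        else:
            raise ValueError(f"unknown layer {layer!r}")
    matrix = pd.DataFrame(rows).T.fillna(0.0)
    matrix = matrix.loc[[p.fiber_id for p in fibers]]  # preserve input order
    return matrix


@dataclass
class PhyloglycomicGrouping:
    """Result of hierarchical clustering of fiber profiles."""

    dendrogram: np.ndarray  # scipy linkage matrix (merge heights in distance units)
    labels: dict[str, str]  # fiber_id -> group id ("A", "B", ...)
    k: int
    linkage_method: str
    cut_height: float
    fiber_ids: list[str]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for fid, g in self.labels.items():
            out.setdefault(g, []).append(fid)
        return out


def _letters(i: int) -> str:
    # A, B, ..., Z, AA, AB, ...
    name = ""
    i_ = i
    while True:
        name = chr(ord("A") + i_ % 26) + name
        i_ = i_ // 26 - 1
        if i_ < 0:
            return name


def phyloglycomic_cluster(matrix: pd.DataFrame, k: int,
                          linkage_method: str = "complete") -> PhyloglycomicGrouping:
    """Agglomerative clustering of fibers on Euclidean distance.

    Group ids are assigned ``A, B, C, ...`` by dendrogram left-to-right
    leaf order; ties everywhere break by lowest input index (scipy's
    deterministic ordering on the given input order).
    """
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 fibers to cluster")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} fibers")
    dists = pdist(matrix.to_numpy(), metric="euclidean")
    Z = hierarchy.linkage(dists, method=linkage_method)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if k == 1:
        cut = float(Z[-1, 2])
    elif k == n:
        cut = 0.0
    else:
        cut = float(Z[n - k - 1, 2])
    leaf_order = hierarchy.leaves_list(Z)
    seen: dict[int, str] = {}
    for leaf in leaf_order:
        c = raw[leaf]
        if c not in seen:
            seen[c] = _letters(len(seen))
    labels = {matrix.index[i]: seen[raw[i]] for i in range(n)}
    return PhyloglycomicGrouping(
        dendrogram=Z, labels=labels, k=k, linkage_method=linkage_method,
        cut_height=cut, fiber_ids=list(matrix.index),
    )


def suggest_k(matrix: pd.DataFrame, k_range=range(2, 8),
              linkage_method: str = "complete") -> int:
    """Silhouette-based suggestion for the number of phyloglycomic groups.

    Advisory only — it is never applied automatically, since the natural
    group count of a fiber panel is a judgment call.
    """
    from sklearn.metrics import silhouette_score

    n = matrix.shape[0]
    best_k, best_score = None, -np.inf
    X = matrix.to_numpy()
    Z = hierarchy.linkage(pdist(X), method=linkage_method)
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise ValueError("no candidate k admits a silhouette score")
    return best_k


def size_distribution_summary(p: GlycanProfile, threshold_label: str = ">1000"
                              ) -> dict[str, object]:
    """Dominant size bin and the fraction above the large-size threshold.

    Bins are assumed listed smallest-first; on a tie the lowest (smallest
    size range, first listed) bin wins. The default threshold marks
    molecules above 1,000 kDa.
    """
    if not p.size_bins:
        raise ValueError(f"{p.fiber_id}: size_bins is empty")
    labels = list(p.size_bins.keys())
    values = np.array([p.size_bins[l] for l in labels])
    dominant = labels[int(np.argmax(values))]  # argmax takes first on ties
    above = float(p.size_bins.get(threshold_label, 0.0))
    cumulative = dict(zip(labels, np.cumsum(values)))
    return {
        "fiber_id": p.fiber_id,
        "dominant_bin": dominant,
        "fraction_above_threshold": above,
        "cumulative": cumulative,
    }


def classify_novel_fiber(novel: GlycanProfile, reference_fibers: list[GlycanProfile],
                         grouping: PhyloglycomicGrouping, layer: str = "mono",
                         distance: str = "euclidean") -> dict[str, object]:
    """Assign a novel fiber to the nearest phyloglycomic group.

    Nearest = minimum average distance to group members; Euclidean on the
    monosaccharide layer, Bray-Curtis on the linkage layer. Features
    unseen in the references are zero-filled on both sides; if the novel
    fiber sits farther from every group than any two references are from
    each other, a maximal-distance warning is logged.
    """
    ref_matrix = build_profile_matrix(reference_fibers, layer=layer)
    if layer == "mono":
        novel_vec = dict(novel.mono_abundance)
    else:
        if novel.linkage_norm is None:
            raise ValueError("novel fiber lacks normalized linkages for linkage layer")
        novel_vec = dict(novel.linkage_norm)
    features = sorted(set(ref_matrix.columns) | set(novel_vec))
    ref = ref_matrix.reindex(columns=features, fill_value=0.0)
    x = np.array([novel_vec.get(f, 0.0) for f in features])
    metric = {"euclidean": _euc, "braycurtis": _bc}[distance]
    dist_to_ref = {fid: float(metric(x, ref.loc[fid].to_numpy())) for fid in ref.index}
    group_distances = {
        g: float(np.mean([dist_to_ref[fid] for fid in members]))
        for g, members in grouping.groups().items()
    }
    ranked = sorted(group_distances.items(), key=lambda kv: (kv[1], kv[0]))
    predicted = ranked[0][0]
    ref_pair_max = float(pdist(ref.to_numpy(), metric=distance).max())
    off_support = ranked[0][1] > ref_pair_max
    if off_support:
        logger.warning("novel fiber %s is farther from every group than any reference "
                       "pair; prediction is extrapolated", novel.fiber_id)
    return {
        "predicted_group": predicted,
        "group_distances": dict(ranked),
        "fiber_distances": dist_to_ref,
        "off_support": off_support,
    }


def check_linkage_closure(p: GlycanProfile, tol: float = 1e-12) -> None:
    """Assert per-parent conservation: normalized subsums == mono shares."""
    assert p.linkage_norm is not None
    for m, share in p.mono_abundance.items():
        sub = sum(v for l, v in p.linkage_norm.items()
                  if p.linkage_parent.get(l, l.replace("unannotated-", "")) == m)
        if abs(sub - share) > tol:
            raise AssertionError(
                f"{p.fiber_id}: linkage mass {sub} != mono share {share} for {m}"
            )
    total = sum(p.linkage_norm.values())
    if abs(total - sum(p.mono_abundance.values())) > 100 * tol:
        raise AssertionError(f"{p.fiber_id}: total linkage mass {total} not conserved")
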