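"""Ordination-shift analysis: the determinism statistic.

After a single joint NMDS across all donors and treatments, each donor's
untreated sample is shifted to the origin and all of that donor's
samples are translated by the same shift. The displacement vector of a
fiber treatment then describes how that fiber moved the donor relative
to no treatment. For one fiber, the mean pairwise cosine similarity of
displacement vectors across donors measures how deterministic (glycan-
driven) the response is: 1 means every donor moved the same way, 0 means
directions were unrelated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from glycoferm.io import UNTREATED
from glycoferm.ecology import OrdinationResult

logger = logging.getLogger("glycoferm")


@dataclass
class DisplacementSet:
    """Per-(donor, treatment) displacement vectors after origin shift."""

    entries: dict[tuple[str, str], np.ndarray]
    origin_policy: str = "untreated-at-origin"

    def treatments(self) -> list[str]:
        return sorted({t for (_, t) in self.entries})

    def donors(self) -> list[str]:
        return sorted({d for (d, _) in self.entries})

    def vectors_for(self, treatment: str) -> dict[str, np.ndarray]:
        return {d: v for (d, t), v in self.entries.items() if t == treatment}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"donor_id": d, "treatment": t,
             **{f"axis{i + 1}": float(x) for i, x in enumerate(v)}}
            for (d, t), v in self.entries.items()
        ]
        return pd.DataFrame(rows)


def normalize_shifts(ordination: OrdinationResult | pd.DataFrame,
                     metadata: pd.DataFrame) -> DisplacementSet:
    """Shift each donor's untreated coordinates to (0, 0).

    ``metadata`` is indexed by sample id with ``donor_id`` and
    ``treatment`` columns; every donor must have exactly one untreated
    sample among the ordinated samples. Returns displacements for every
    (donor, treatment) including untreated, which is exactly the zero
    vector.
    """
    coords = (ordination.coordinates if isinstance(ordination, OrdinationResult)
              else ordination)
    entries: dict[tuple[str, str], np.ndarray] = {}
    meta = metadata.loc[coords.index]
    for donor, sub in meta.groupby("donor_id", sort=True):
        ctrl = sub.index[sub["treatment"] == UNTREATED]
        if len(ctrl) == 0:
            raise ValueError(f"donor {donor!r} has no untreated sample in the ordination")
        if len(ctrl) > 1:
            raise ValueError(f"donor {donor!r} has {len(ctrl)} untreated samples")
        origin = coords.loc[ctrl[0]].to_numpy(dtype=float)
        for sid in sub.index:
            t = str(sub.loc[sid, "treatment"])
            disp = coords.loc[sid].to_numpy(dtype=float) - origin
            if t == UNTREATED:
                disp = np.zeros_like(disp)
            entries[(str(donor), t)] = disp
    return DisplacementSet(entries=entries)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); raises on a zero-norm vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


def mean_pairwise_cosine(ds: DisplacementSet, treatment: str
                         ) -> tuple[float, int, int]:
    """Mean cosine similarity over all unordered donor pairs for one fiber.

    Donors with zero displacement are excluded (cosine is undefined at
    the origin); returns ``(score, n_pairs, n_excluded)``.
    """
    vecs = ds.vectors_for(treatment)
    usable = {d: v for d, v in vecs.items() if np.linalg.norm(v) > 0}
    n_excluded = len(vecs) - len(usable)
    if n_excluded:
        logger.warning("%s: excluded %d zero-displacement donor(s)", treatment, n_excluded)
    if len(usable) < 2:
        raise ValueError(f"{treatment!r}: need >= 2 donors with nonzero displacement")
    donors = sorted(usable)
    sims = [cosine_similarity(usable[a], usable[b])
            for a, b in itertools.combinations(donors, 2)]
    return float(np.mean(sims)), len(sims), n_excluded


def score_all_treatments(ds: DisplacementSet) -> pd.DataFrame:
    """Determinism score table for every non-untreated treatment."""
    rows = []
    for t in ds.treatments():
        if t == UNTREATED:
            continue
        try:
            score, n_pairs, n_excl = mean_pairwise_cosine(ds, t)
        except ValueError:
            score, n_pairs, n_excl = np.nan, 0, len(ds.vectors_for(t))
        rows.append({"treatment": t, "cosine_score": score,
                     "n_pairs": n_pairs, "n_excluded": n_excl})
    return pd.DataFrame(rows).set_index("treatment")


def kmeans_trajectories(ds: DisplacementSet, k: int, seed: int = 0) -> dict[str, int]:
    """k-means clustering of per-treatment mean displacement vectors.

    Treatments whose donor displacements average to similar trajectories
    share a cluster. Ten restarts, best inertia kept; deterministic
    given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    treatments = [t for t in ds.treatments() if t != UNTREATED]
    means = np.array([
        np.mean(list(ds.vectors_for(t).values()), axis=0) for t in treatments
    ])
    if k > len(treatments):
        raise ValueError("k exceeds the number of treatments")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assignments = km.fit_predict(means)
    return {t: int(c) for t, c in zip(treatments, assignments)}
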