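"""End-to-end workflows chaining the analysis stages.

These are the compositions the CLI subcommands and the validation
scripts run: simulate a study, ordinate end-point profiles, normalize
shifts to each donor's untreated control, and score per-fiber
determinism; sweep the generator's determinism weight to map the
recovery surface of the cosine statistic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from glycoferm.ecology import nmds, pairwise_distances
from glycoferm.io import FermentationDataset
from glycoferm.shifts import normalize_shifts, score_all_treatments
from glycoferm.simulate import SimulationConfig, simulate_study


def endpoint_shift_scores(ds: FermentationDataset, layer: str = "scfa",
                          metric: str = "braycurtis", time_h: float = 24.0,
                          dims: int = 2, n_restarts: int = 1, seed: int = 0,
                          max_iter: int = 150) -> pd.DataFrame:
    """Joint NMDS of end-point profiles, per-donor origin shift, cosine scores.

    ``layer`` selects SCFA profiles (Bray-Curtis by default) or community
    taxa (weighted UniFrac when a tree is present).
    """
    if layer == "scfa":
        table = ds.metabolite_table(time_h=time_h)
        tree = None
    elif layer == "community":
        table = ds.taxa_table(time_h=time_h)
        tree = ds.tree
    else:
        raise ValueError(f"unknown layer {layer!r}")
    dm = pairwise_distances(table, metric=metric, tree=tree)
    ordination = nmds(dm, dims=dims, n_restarts=n_restarts, seed=seed,
                      max_iter=max_iter)
    meta = ds.metadata().loc[table.index]
    displacements = normalize_shifts(ordination, meta)
    return score_all_treatments(displacements)


def determinism_surface(base_cfg: SimulationConfig | None = None,
                        lams=(0.0, 0.25, 0.5, 0.75, 1.0),
                        seeds=range(20), noise_sd: float | None = None
                        ) -> pd.DataFrame:
    """Mean cosine score per determinism weight, averaged over seeds.

    For each (lambda, seed) the full generator runs, end-point SCFA
    profiles are ordinated, and the mean of the per-fiber cosine scores
    is recorded. The returned frame has one row per lambda with the
    seed-averaged score.
    """
    if base_cfg is None:
        base_cfg = SimulationConfig()
    rows = []
    for lam in lams:
        per_seed = []
        for seed in seeds:
            overrides = {"lam": float(lam), "seed": int(seed)}
            if noise_sd is not None:
                overrides["noise_sd"] = float(noise_sd)
            cfg = dataclasses.replace(base_cfg, **overrides)
            _, _, ds = simulate_study(cfg)
            scores = endpoint_shift_scores(ds, time_h=max(cfg.time_points),
                                           seed=seed)
            per_seed.append(float(scores["cosine_score"].mean()))
        rows.append({"lam": float(lam), "mean_cosine": float(np.mean(per_seed)),
                     "n_seeds": len(per_seed)})
    return pd.DataFrame(rows).set_index("lam")
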