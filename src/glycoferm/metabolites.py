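"""SCFA end-product summaries.

Max-scaling and two-way clustering for heatmap displays, the
butyrate:propionate ratio used to color ordinations, donor-penetrance
CCDF curves (what fraction of donors reaches at least a given metabolite
level), and taxon-metabolite Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from glycoferm.io import FermentationDataset, SampleRecord

logger = logging.getLogger("glycoferm")


def scale_to_max(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each metabolite column so its maximum measured value is 100%.

    All-zero columns stay zero with a warning. Idempotent up to the
    per-column positive rescaling it performs.
    """
    if (table.to_numpy() < 0).any():
        raise ValueError("negative concentrations")
    out = table.copy().astype(float)
    for col in out.columns:
        m = out[col].max()
        if m > 0:
            out[col] = out[col] / m * 100.0
        else:
            logger.warning("metabolite %r is all-zero; left unscaled", col)
    return out


@dataclass
class HeatmapOrdering:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def cluster_heatmap_data(scaled: pd.DataFrame, linkage_method: str = "complete"
                         ) -> HeatmapOrdering:
    """Independent hierarchical clustering of rows and columns (Euclidean)."""
    if scaled.shape[0] < 2 or scaled.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if not np.isfinite(scaled.to_numpy()).all():
        raise ValueError("non-finite values")
    rowZ = hierarchy.linkage(pdist(scaled.to_numpy()), method=linkage_method)
    colZ = hierarchy.linkage(pdist(scaled.to_numpy().T), method=linkage_method)
    row_order = [scaled.index[i] for i in hierarchy.leaves_list(rowZ)]
    col_order = [scaled.columns[i] for i in hierarchy.leaves_list(colZ)]
    return HeatmapOrdering(row_order, col_order, rowZ, colZ)


def butyrate_propionate_ratio(record: SampleRecord) -> float:
    """Butyrate / propionate; zero propionate -> NaN with a warning."""
    for m in ("butyrate", "propionate"):
        if m not in record.metabolites:
            raise KeyError(f"{record.sample_id}: {m} not measured")
    prop = record.metabolites["propionate"]
    if prop == 0:
        logger.warning("%s: propionate is 0; ratio undefined", record.sample_id)
        return float("nan")
    return record.metabolites["butyrate"] / prop


@dataclass
class CCDFCurve:
    """Complementary CDF of a metabolite across donors.

    ``survival[i]`` is the fraction of donors whose concentration is at
    least ``thresholds[i]`` (>= convention, right-continuous steps).
    """

    metabolite: str
    time_h: float
    thresholds: np.ndarray  # ascending, ug/mL
    survival: np.ndarray  # fractions in [0, 1], non-increasing
    n_donors: int
    values: np.ndarray | None = None  # raw per-donor values, for off-grid S(c)
    step_convention: str = "right-continuous; S(c) = P(value >= c)"

    def survival_at(self, c: float) -> float:
        if self.values is not None:
            return float(np.mean(self.values >= c))
        # fall back to the right-continuous step function on the grid
        ok = self.survival[self.thresholds >= c]
        return float(ok[0]) if ok.size else 0.0


def ccdf_curve(values, metabolite: str, time_h: float,
               grid=None) -> CCDFCurve:
    """Empirical donor-penetrance curve S(c) = (1/N) #{donors >= c}.

    Evaluated at all observed values plus an optional extra grid.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no donor values")
    if (values < 0).any():
        raise ValueError("negative concentrations")
    thresholds = np.unique(values if grid is None
                           else np.concatenate([values, np.asarray(grid, dtype=float)]))
    survival = np.array([(values >= c).mean() for c in thresholds])
    return CCDFCurve(metabolite=metabolite, time_h=time_h, thresholds=thresholds,
                     survival=survival, n_donors=int(values.size), values=values)


def level_at_survival(curve: CCDFCurve, q: float) -> float:
    """Largest threshold c with S(c) >= q (the level at least q of donors reach)."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    ok = curve.thresholds[curve.survival >= q]
    if ok.size == 0:
        raise ValueError(f"no threshold reaches survival {q}")
    return float(ok.max())


def donor_endpoint_values(ds: FermentationDataset, treatment: str, metabolite: str,
                          time_h: float) -> pd.Series:
    """Per-donor concentration of one metabolite for one treatment/time."""
    vals = {
        r.donor_id: r.metabolites.get(metabolite, np.nan)
        for r in ds.records
        if r.treatment == treatment and r.time_h == time_h
    }
    return pd.Series(vals).dropna().sort_index()


def taxon_metabolite_correlation(ds: FermentationDataset, taxon: str, metabolite: str,
                                 time_h: float) -> tuple[float, float, int]:
    """Pearson correlation of a taxon's relative abundance with a metabolite.

    Pairs observations across samples at one time point; two-sided p
    from the t transform. Zero variance in either variable is an error.
    """
    xs, ys = [], []
    for r in ds.records:
        if r.time_h != time_h or r.taxa_abundance is None:
            continue
        if taxon not in r.taxa_abundance.index or metabolite not in r.metabolites:
            continue
        xs.append(float(r.taxa_abundance[taxon]))
        ys.append(float(r.metabolites[metabolite]))
    n = len(xs)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    x = np.array(xs)
    y = np.array(ys)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n
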