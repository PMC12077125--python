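"""Domain containers and on-disk formats for the fiber fermentation pipeline.

The pipeline operates on three kinds of tables: fiber glycomic profiles
(monosaccharide compositions, linkage peak areas with parent-sugar
annotations, size-bin distributions), long-format fermentation sample
records (donor x treatment x time, carrying community, metabolite, OD and
pH observations), and phylogenies over the community taxa. Everything on
disk is delimited text (TSV/CSV) or Newick; compositions are stored as
fractions summing to 1 — percentage rendering is presentation-layer only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

logger = logging.getLogger("glycoferm")

CLOSURE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GlycanProfile:
    """One fiber's glycomic characterization.

    Parameters
    ----------
    fiber_id : str
        Fiber identifier (e.g. ``"hs-Oat"``).
    mono_abundance : dict
        Monosaccharide name -> relative abundance (fractions, sum to 1).
    linkage_raw : dict
        Linkage name (e.g. ``"4-Glc"``) -> raw peak area (arbitrary units).
        Raw areas carry ionization bias and deliberately do not respect
        monosaccharide closure until normalized.
    linkage_parent : dict
        Linkage name -> parent monosaccharide name.
    linkage_norm : dict or None
        Linkage name -> relative abundance after per-parent rescaling to
        the monosaccharide composition; ``None`` until computed.
    size_bins : dict
        Size-range label (kDa interval) -> fraction of molecules.
    group_label : str or None
        Phyloglycomic group id, when assigned or known from simulation.
    """

    fiber_id: str
    mono_abundance: dict[str, float]
    linkage_raw: dict[str, float] = field(default_factory=dict)
    linkage_parent: dict[str, str] = field(default_factory=dict)
    linkage_norm: dict[str, float] | None = None
    size_bins: dict[str, float] = field(default_factory=dict)
    group_label: str | None = None

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated invariant."""
        mono = np.array(list(self.mono_abundance.values()), dtype=float)
        if (mono < 0).any():
            raise ValueError(f"{self.fiber_id}: negative monosaccharide abundance")
        if abs(mono.sum() - 1.0) > CLOSURE_TOL:
            raise ValueError(
                f"{self.fiber_id}: monosaccharide abundances sum to {mono.sum()}, not 1"
            )
        for link in self.linkage_raw:
            parent = self.linkage_parent.get(link)
            if parent is None or parent not in self.mono_abundance:
                raise ValueError(
                    f"{self.fiber_id}: linkage {link!r} has no parent in mono_abundance"
                )
        if self.size_bins:
            sizes = np.array(list(self.size_bins.values()), dtype=float)
            if (sizes < 0).any():
                raise ValueError(f"{self.fiber_id}: negative size-bin fraction")
            if abs(sizes.sum() - 1.0) > CLOSURE_TOL:
                raise ValueError(
                    f"{self.fiber_id}: size-bin fractions sum to {sizes.sum()}, not 1"
                )


@dataclass
class SampleRecord:
    """One fermentation sample: donor x treatment x time point."""

    sample_id: str
    donor_id: str
    treatment: str  # fiber_id or "untreated"
    time_h: float
    taxa_abundance: pd.Series | None = None  # relative abundances over taxon ids
    metabolites: dict[str, float] = field(default_factory=dict)
    od600: float = float("nan")
    ph: float = float("nan")

    def validate(self) -> None:
        if self.taxa_abundance is not None:
            v = self.taxa_abundance.to_numpy(dtype=float)
            if (v < 0).any():
                raise ValueError(f"{self.sample_id}: negative taxa abundance")
            if v.size and abs(v.sum() - 1.0) > CLOSURE_TOL:
                raise ValueError(
                    f"{self.sample_id}: taxa abundances sum to {v.sum()}, not 1"
                )
        for name, conc in self.metabolites.items():
            if conc < 0:
                raise ValueError(f"{self.sample_id}: negative {name} concentration")


UNTREATED = "untreated"


@dataclass
class FermentationDataset:
    """Collection of sample records with taxonomy and optional phylogeny."""

    records: list[SampleRecord]
    taxonomy: dict[str, str] = field(default_factory=dict)  # taxon id -> lineage label
    tree: TreeNode | None = None

    # -- wide-format accessors -------------------------------------------
    def metadata(self) -> pd.DataFrame:
        """Per-sample metadata (sample_id, donor, treatment, time, OD, pH)."""
        rows = [
            {
                "sample_id": r.sample_id,
                "donor_id": r.donor_id,
                "treatment": r.treatment,
                "time_h": r.time_h,
                "od600": r.od600,
                "ph": r.ph,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows).set_index("sample_id")

    def taxa_table(self, time_h: float | None = None) -> pd.DataFrame:
        """Samples x taxa relative-abundance matrix (optionally one time point)."""
        recs = self._select(time_h)
        rows = {r.sample_id: r.taxa_abundance for r in recs if r.taxa_abundance is not None}
        return pd.DataFrame(rows).T.fillna(0.0)

    def metabolite_table(self, time_h: float | None = None) -> pd.DataFrame:
        """Samples x metabolites concentration matrix (ug/mL)."""
        recs = self._select(time_h)
        rows = {r.sample_id: r.metabolites for r in recs if r.metabolites}
        return pd.DataFrame(rows).T.fillna(0.0)

    def _select(self, time_h: float | None) -> list[SampleRecord]:
        if time_h is None:
            return self.records
        return [r for r in self.records if r.time_h == time_h]

    @property
    def donors(self) -> list[str]:
        return sorted({r.donor_id for r in self.records})

    @property
    def treatments(self) -> list[str]:
        return sorted({r.treatment for r in self.records})

    @property
    def time_points(self) -> list[float]:
        return sorted({r.time_h for r in self.records})


@dataclass
class AnalysisConfig:
    """Knobs shared by the downstream analysis stages.

    The distances default to the study design: weighted UniFrac for
    communities, Bray-Curtis for SCFA profiles (Gower available), and
    Euclidean for glycomics.
    """

    community_distance: str = "weighted_unifrac"
    scfa_distance: str = "braycurtis"
    glycomics_distance: str = "euclidean"
    linkage_method: str = "complete"
    nmds_dims: int = 2
    nmds_restarts: int = 4
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    reference_treatment: str = "GOS"
    endpoint_h: float = 24.0

    def __post_init__(self) -> None:
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.nmds_dims < 2:
            raise ValueError("nmds_dims must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_feature_table(path: str | Path, rows_are_features: bool = True) -> pd.DataFrame:
    """Read a labeled numeric matrix from delimited text.

    TSV vs CSV is auto-detected by extension. The first row is the header,
    the first column holds row labels. Duplicate labels, ragged rows, and
    non-numeric payload cells are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _delimiter(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
    cols = header_line.split(sep)[1:]
    dupes = [c for c in set(cols) if cols.count(c) > 1]
    if dupes:
        raise ValueError(f"duplicate column label(s): {sorted(dupes)}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ValueError(f"ragged rows in {path.name}: {exc}") from exc
    if df.shape[0] == 0:
        raise ValueError(f"no data rows in {path.name}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row label(s): {dupes}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric payload in {path.name}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"missing/ragged cells in {path.name}")
    if not rows_are_features:
        df = df.T
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_delimiter(path))


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> TreeNode:
    """Read a rooted phylogeny; validate leaves and branch lengths.

    Missing branch lengths default to 0 with a logged warning; negative
    branch lengths and duplicate leaf names are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty Newick file: {path.name}")
    tree = TreeNode.read([text])
    return validate_tree(tree)


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    if not text.strip():
        raise ValueError("empty Newick string")
    return validate_tree(TreeNode.read([text]))


def validate_tree(tree: TreeNode) -> TreeNode:
    leaves = [t.name for t in tree.tips()]
    if len(leaves) != len(set(leaves)):
        raise ValueError("duplicate leaf names in tree")
    n_missing = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
            if not node.is_root():
                n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length at {node.name!r}")
    if n_missing:
        logger.warning("%d branch length(s) missing; set to 0", n_missing)
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


# ---------------------------------------------------------------------------
# Dataset (de)serialization — long table on disk, wide accessors in memory
# ---------------------------------------------------------------------------

def write_dataset(ds: FermentationDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(ds.metadata(), outdir / "samples.tsv")
    taxa = ds.taxa_table()
    if not taxa.empty:
        write_feature_table(taxa.T, outdir / "taxa.tsv")  # taxa x samples
    met = ds.metabolite_table()
    if not met.empty:
        write_feature_table(met.T, outdir / "metabolites.tsv")
    if ds.taxonomy:
        pd.Series(ds.taxonomy, name="lineage").rename_axis("taxon_id").to_csv(
            outdir / "taxonomy.tsv", sep="\t"
        )
    if ds.tree is not None:
        write_newick(ds.tree, outdir / "tree.nwk")


def read_dataset(indir: str | Path) -> FermentationDataset:
    indir = Path(indir)
    # treatment / donor columns are strings, so no numeric coercion here
    meta = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0)
    taxa = None
    if (indir / "taxa.tsv").exists():
        taxa = read_feature_table(indir / "taxa.tsv").T  # samples x taxa
    met = None
    if (indir / "metabolites.tsv").exists():
        met = read_feature_table(indir / "metabolites.tsv").T
    records = []
    for sid, row in meta.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(sid),
                donor_id=str(row["donor_id"]),
                treatment=str(row["treatment"]),
                time_h=float(row["time_h"]),
                taxa_abundance=taxa.loc[sid] if taxa is not None and sid in taxa.index else None,
                metabolites=met.loc[sid].to_dict() if met is not None and sid in met.index else {},
                od600=float(row.get("od600", np.nan)),
                ph=float(row.get("ph", np.nan)),
            )
        )
    taxonomy: dict[str, str] = {}
    if (indir / "taxonomy.tsv").exists():
        taxonomy = (
            pd.read_csv(indir / "taxonomy.tsv", sep="\t", index_col=0)["lineage"].to_dict()
        )
    tree = read_newick(indir / "tree.nwk") if (indir / "tree.nwk").exists() else None
    return FermentationDataset(records=records, taxonomy=taxonomy, tree=tree)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(ds: FermentationDataset, strict: bool = False) -> list[str]:
    """Check dataset integrity; return a list of violation messages.

    Checks: exactly one untreated control per donor per time point, taxa
    present in records but absent from the tree, negative values, and
    abundance vectors failing closure. With ``strict=True`` the first
    violation raises ``ValueError``.
    """
    violations: list[str] = []

    def report(msg: str) -> None:
        if strict:
            raise ValueError(msg)
        violations.append(msg)

    times = ds.time_points
    for donor in ds.donors:
        for t in times:
            n_ctrl = sum(
                1
                for r in ds.records
                if r.donor_id == donor and r.time_h == t and r.treatment == UNTREATED
            )
            if n_ctrl == 0:
                report(f"donor {donor!r} lacks an untreated control at {t} h")
            elif n_ctrl > 1:
                report(f"donor {donor!r} has {n_ctrl} untreated controls at {t} h")

    tree_leaves = {t.name for t in ds.tree.tips()} if ds.tree is not None else None
    for r in ds.records:
        try:
            r.validate()
        except ValueError as exc:
            report(str(exc))
        if tree_leaves is not None and r.taxa_abundance is not None:
            missing = [t for t in r.taxa_abundance.index if t not in tree_leaves]
            if missing:
                report(f"{r.sample_id}: taxa absent from tree: {missing}")

    return violations


def write_fibers(fibers: Sequence[GlycanProfile], outdir: str | Path) -> None:
    """Write fiber glycomic profiles as a directory of TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mono = pd.DataFrame({p.fiber_id: p.mono_abundance for p in fibers}).T.fillna(0.0)
    write_feature_table(mono.rename_axis("fiber_id"), outdir / "fibers_mono.tsv")
    raw = pd.DataFrame({p.fiber_id: p.linkage_raw for p in fibers}).T.fillna(0.0)
    if not raw.empty:
        write_feature_table(raw.rename_axis("fiber_id"), outdir / "fibers_linkage_raw.tsv")
        parents: dict[str, str] = {}
        for p in fibers:
            parents.update(p.linkage_parent)
        pd.Series(parents, name="parent").rename_axis("linkage").to_csv(
            outdir / "linkage_parents.tsv", sep="\t")
    size = pd.DataFrame({p.fiber_id: p.size_bins for p in fibers}).T.fillna(0.0)
    if not size.empty:
        write_feature_table(size.rename_axis("fiber_id"), outdir / "fibers_size_bins.tsv")
    groups = {p.fiber_id: p.group_label for p in fibers if p.group_label}
    if groups:
        pd.Series(groups, name="group").rename_axis("fiber_id").to_csv(
            outdir / "fiber_groups.tsv", sep="\t")


def read_fibers(indir: str | Path) -> list[GlycanProfile]:
    """Read fiber profiles written by :func:`write_fibers`."""
    indir = Path(indir)
    mono = read_feature_table(indir / "fibers_mono.tsv")
    raw = parents = size = groups = None
    if (indir / "fibers_linkage_raw.tsv").exists():
        raw = read_feature_table(indir / "fibers_linkage_raw.tsv")
        parents = pd.read_csv(indir / "linkage_parents.tsv", sep="\t",
                              index_col=0)["parent"].to_dict()
    if (indir / "fibers_size_bins.tsv").exists():
        size = read_feature_table(indir / "fibers_size_bins.tsv")
    if (indir / "fiber_groups.tsv").exists():
        groups = pd.read_csv(indir / "fiber_groups.tsv", sep="\t",
                             index_col=0)["group"].to_dict()
    fibers = []
    for fid in mono.index:
        mono_row = {k: v for k, v in mono.loc[fid].items() if v > 0}
        raw_row = ({k: v for k, v in raw.loc[fid].items() if v > 0}
                   if raw is not None and fid in raw.index else {})
        fibers.append(
            GlycanProfile(
                fiber_id=str(fid),
                mono_abundance=mono_row,
                linkage_raw=raw_row,
                linkage_parent={k: parents[k] for k in raw_row} if parents else {},
                size_bins=(size.loc[fid].to_dict()
                           if size is not None and fid in size.index else {}),
                group_label=groups.get(fid) if groups else None,
            )
        )
    return fibers


def write_manifest(path: str | Path, command: str, params: Mapping, seed: int | None) -> None:
    """Write the JSON run manifest every CLI subcommand emits."""
    from glycoferm import __version__

    payload = {
        "command": command,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "seed": seed,
        "glycoferm_version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    return v
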