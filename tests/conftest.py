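import numpy as np
import pandas as pd
import pytest

from glycoferm.io import GlycanProfile, SampleRecord, FermentationDataset, UNTREATED
from glycoferm.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by read-only tests."""
    cfg = SimulationConfig(n_donors=5, fibers_per_group=(1, 1, 1, 1, 1), seed=42)
    fibers, donors, ds = simulate_study(cfg)
    return cfg, fibers, donors, ds


@pytest.fixture
def tiny_dataset():
    """Hand-built two-donor dataset with untreated controls."""
    taxa = ["t1", "t2", "t3"]

    def rec(donor, treatment, time_h, abund, mets):
        return SampleRecord(
            sample_id=f"{donor}.{treatment}.{time_h}",
            donor_id=donor,
            treatment=treatment,
            time_h=time_h,
            taxa_abundance=pd.Series(abund, index=taxa, dtype=float),
            metabolites=mets,
            od600=0.3,
            ph=6.5,
        )

    records = [
        rec("d1", UNTREATED, 24.0, [0.5, 0.3, 0.2], {"butyrate": 100, "propionate": 50}),
        rec("d1", "fiberX", 24.0, [0.7, 0.2, 0.1], {"butyrate": 900, "propionate": 100}),
        rec("d2", UNTREATED, 24.0, [0.2, 0.4, 0.4], {"butyrate": 120, "propionate": 60}),
        rec("d2", "fiberX", 24.0, [0.4, 0.3, 0.3], {"butyrate": 800, "propionate": 90}),
    ]
    return FermentationDataset(records=records, taxonomy={t: "g" for t in taxa})


def make_profile(fiber_id="f", mono=None, raw=None, parents=None, size=None):
    mono = mono if mono is not None else {"Glc": 0.8, "Xyl": 0.2}
    return GlycanProfile(
        fiber_id=fiber_id,
        mono_abundance=mono,
        linkage_raw=raw or {},
        linkage_parent=parents or {},
        size_bins=size or {},
    )
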