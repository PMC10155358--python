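import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from oxbskit.hmc_estimation import estimate_hmc, merge_paired
from oxbskit.meth_io import ContrastDesign
from oxbskit.synthetic_cohort import (
    PERFECT_CHEMISTRY,
    CoverageModel,
    RegionEffect,
    TruthSpec,
    simulate_counts,
)


def uniform_cpg_map(n_sites: int, spacing: int = 50, chrom: str = "chr1") -> pd.DataFrame:
    pos = 10_000 + spacing * np.arange(1, n_sites + 1)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+"})


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_design():
    samples = [f"s{i + 1:02d}" for i in range(12)]
    groups = dict(zip(samples, ["control"] * 6 + ["case"] * 6))
    return ContrastDesign("unit", groups)


@pytest.fixture
def planted_cohort(small_design):
    """6v6 cohort, 120 CpGs, one planted hyper-5mC region, perfect chemistry."""
    cpg_map = uniform_cpg_map(120)
    pos = cpg_map["pos"].to_numpy()
    region = RegionEffect("chr1", int(pos[40]), int(pos[59]) + 2, "5mC", 0.35)
    truth = TruthSpec(
        cpg_map=cpg_map,
        group_labels=list(small_design.groups.values()),
        regions=[region],
        baseline_m=0.4,
        baseline_h=0.2,
        coverage=CoverageModel(40.0),
        chemistry=PERFECT_CHEMISTRY,
        seed=11,
    )
    tables = simulate_counts(truth)
    cohort = {
        s: estimate_hmc(merge_paired(t["bs"], t["ox"], min_cov=5))
        for s, t in tables.items()
    }
    return cohort, small_design, region
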