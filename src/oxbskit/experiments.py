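"""Canned simulation studies validating the pipeline's statistical claims.

Each function sets up a synthetic cohort under stated study conditions,
runs the relevant part of the pipeline, and returns the summary quantity:

* subtraction-estimator recovery of a known 5hmC level;
* family-wise null behaviour of the DMR caller (no planted effects);
* recall of planted 5mC / 5hmC DMRs at the standard thresholds
  (|diff| > 0.2 for 5mC, > 0.1 for 5hmC, q < 0.05);
* attenuation of the combined-bisulfite AUC when an opposing 5hmC shift
  partially cancels a 5mC shift;
* global anti-correlation between region-level 5mC and 5hmC differences
  under coupled opposite-sign effects.

Problem sizes are desk-scale (thousands of CpGs, 10 vs 10 samples) so the
studies run in minutes; they probe properties of the method, not the
cohort-specific tallies of any particular dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dmr_calling, hmc_estimation, synthetic_cohort
from .biomarker_screen import auc, profile_correlation, region_sample_means
from .meth_io import ContrastDesign
from .synthetic_cohort import (
    PERFECT_CHEMISTRY,
    ChemistryParams,
    CoverageModel,
    RegionEffect,
    TruthSpec,
)


def _uniform_map(n_sites: int, spacing: int = 50, chrom: str = "chr1") -> pd.DataFrame:
    pos = 10_000 + spacing * np.arange(1, n_sites + 1)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+"})


def _design(n_per_group: int) -> ContrastDesign:
    labels = ["control"] * n_per_group + ["case"] * n_per_group
    samples = [f"s{i + 1:02d}" for i in range(2 * n_per_group)]
    return ContrastDesign("sim", dict(zip(samples, labels)))


def _paired_cohort(truth: TruthSpec, min_cov: int = 5) -> dict[str, pd.DataFrame]:
    tables = synthetic_cohort.simulate_counts(truth)
    return {
        s: hmc_estimation.merge_paired(t["bs"], t["ox"], min_cov=min_cov)
        for s, t in tables.items()
    }


def hmc_recovery(
    seed: int, n_sites: int = 1000, coverage: float = 50.0,
    true_h: float = 0.2, true_m: float = 0.5,
) -> float:
    """Mean raw subtraction estimate of 5hmC under perfect chemistry.

    One sample, constant truth across sites; returns mean(h_hat), whose
    bias should vanish (E[beta_BS - beta_oxBS] = h exactly).
    """
    truth = TruthSpec(
        cpg_map=_uniform_map(n_sites),
        group_labels=["control"],
        baseline_m=true_m, baseline_h=true_h,
        coverage=CoverageModel(coverage, dispersion=1e9),  # near-fixed depth
        chemistry=PERFECT_CHEMISTRY,
        seed=seed,
    )
    tables = synthetic_cohort.simulate_counts(truth)["s01"]
    paired = hmc_estimation.merge_paired(tables["bs"], tables["ox"], min_cov=1)
    est = hmc_estimation.estimate_hmc(paired, mode="raw")
    return float(est["h_hat"].mean())


def null_fdr(
    seed: int, n_reps: int = 50, n_sites: int = 2000, n_per_group: int = 10,
    coverage: float = 30.0, marks: tuple[str, ...] = ("5mC", "5hmC"),
) -> float:
    """Fraction of null replicates yielding any significant DMR.

    No effects are planted, so with the q < 0.05 gate plus the effect-size
    threshold essentially no replicate should produce a call.
    """
    design = _design(n_per_group)
    hits = 0
    for rep in range(n_reps):
        truth = TruthSpec(
            cpg_map=_uniform_map(n_sites),
            group_labels=list(design.groups.values()),
            coverage=CoverageModel(coverage),
            seed=seed * 100_003 + rep,
        )
        cohort = _paired_cohort(truth)
        found = False
        for mark in marks:
            dmrs = dmr_calling.call_dmrs(cohort, design, mark)
            if any(d.significant for d in dmrs):
                found = True
                break
        hits += found
    return hits / n_reps


def _region_layout(
    n_regions: int, region_cpgs: int = 10, flank_cpgs: int = 10,
    spacing: int = 50, gap: int = 2000,
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """CpG map of isolated runs: flank / effect region / flank per run.

    Returns the map plus each effect region's (start, end) interval.
    Runs are separated by ``gap`` bp so segmentation treats them apart.
    """
    rows = []
    intervals = []
    cursor = 10_000
    run = 2 * flank_cpgs + region_cpgs
    for _ in range(n_regions):
        pos = cursor + spacing * np.arange(run)
        rows.append(pos)
        intervals.append(
            (int(pos[flank_cpgs]), int(pos[flank_cpgs + region_cpgs - 1]) + 2)
        )
        cursor = int(pos[-1]) + gap
    cpg_map = pd.DataFrame(
        {"chrom": "chr1", "pos": np.concatenate(rows), "strand": "+"}
    )
    return cpg_map, intervals


def dmr_recall(
    seed: int, mark: str, delta: float, n_regions: int = 20,
    n_per_group: int = 10, coverage: float = 30.0,
    m0: float = 0.45, h0: float = 0.25,
) -> float:
    """Recall of planted DMRs: planted regions recovered as significant
    calls of the right mark, direction and location (midpoint inside).

    Planted regions coincide with isolated CpG clusters (as DMRs do), and
    baselines are fixed at moderate levels so the shift is fully realisable
    in both directions without simplex clipping — the study probes the
    caller's power, not boundary saturation or breakpoint placement (those
    have their own tests).
    """
    cpg_map, intervals = _region_layout(n_regions, flank_cpgs=0)
    regions = [
        RegionEffect("chr1", s, e, mark, delta * (1 if k % 2 == 0 else -1))
        for k, (s, e) in enumerate(intervals)
    ]
    design = _design(n_per_group)
    truth = TruthSpec(
        cpg_map=cpg_map, group_labels=list(design.groups.values()),
        regions=regions, baseline_m=m0, baseline_h=h0,
        coverage=CoverageModel(coverage), seed=seed,
    )
    cohort = _paired_cohort(truth)
    calls = [d for d in dmr_calling.call_dmrs(cohort, design, mark) if d.significant]
    recovered = 0
    for reg in regions:
        want = "hyper" if reg.delta > 0 else "hypo"
        for d in calls:
            mid = (d.start + d.end) // 2
            if d.direction == want and reg.start <= mid < reg.end:
                recovered += 1
                break
    return recovered / len(regions)


def attenuation(
    seed: int, n_reps: int = 100, dm: float = 0.3, dh: float = -0.15,
    n_per_group: int = 10, coverage: float = 30.0, region_cpgs: int = 10,
    sample_sd: float = 0.1, m0: float = 0.35, h0: float = 0.40,
) -> dict[str, float]:
    """AUC of the combined BS signal vs the pure 5mC signal per replicate.

    One region per replicate with a planted +dm 5mC shift coupled to a dh
    5hmC shift.  Per-sample regional heterogeneity (sd ``sample_sd``)
    supplies the between-sample biological variance without which every
    AUC saturates.  Returns the fraction of replicates with
    AUC_BS < AUC_5mC and the mean of both AUCs.
    """
    design = _design(n_per_group)
    labels = list(design.groups.values())
    spacing = 50
    pos0, pos1 = 10_000 + spacing, 10_000 + spacing * region_cpgs
    region = ("chr1", pos0, pos1 + 2)
    wins = 0
    auc_bs_all, auc_m_all = [], []
    for rep in range(n_reps):
        truth = TruthSpec(
            cpg_map=_uniform_map(region_cpgs),
            group_labels=labels,
            regions=[RegionEffect(*region, "5mC", dm, coupling=dh)],
            baseline_m=m0, baseline_h=h0,
            coverage=CoverageModel(coverage),
            sample_effect_sd=sample_sd,
            seed=seed * 100_003 + rep,
        )
        cohort = _paired_cohort(truth)
        aucs = {}
        for signal in ("5mC", "BS"):
            means = region_sample_means([region], cohort, signal)
            row = means.iloc[0]
            aucs[signal] = auc(
                row.reindex(design.case_samples), row.reindex(design.control_samples)
            )
        auc_bs_all.append(aucs["BS"])
        auc_m_all.append(aucs["5mC"])
        wins += aucs["BS"] < aucs["5mC"]
    return {
        "frac_bs_below_5mc": wins / n_reps,
        "mean_auc_bs": float(np.mean(auc_bs_all)),
        "mean_auc_5mc": float(np.mean(auc_m_all)),
    }


def anticorrelation(
    seed: int, n_reps: int = 50, n_regions: int = 20, n_per_group: int = 10,
    coverage: float = 30.0, coupling_ratio: float = 0.5,
    m0: float = 0.35, h0: float = 0.40, sample_sd: float = 0.1,
) -> float:
    """Fraction of replicates with negative Pearson r between region-level
    delta-5mC and delta-5hmC when every planted 5mC shift is coupled to an
    opposite-sign 5hmC shift of ``coupling_ratio`` times its size."""
    design = _design(n_per_group)
    labels = list(design.groups.values())
    negatives = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed * 100_003 + rep)
        cpg_map, intervals = _region_layout(n_regions, flank_cpgs=0, gap=2000)
        regions = []
        for s, e in intervals:
            delta = rng.uniform(0.1, 0.3) * rng.choice([-1, 1])
            regions.append(
                RegionEffect("chr1", s, e, "5mC", delta,
                             coupling=-coupling_ratio * delta)
            )
        truth = TruthSpec(
            cpg_map=cpg_map, group_labels=labels, regions=regions,
            baseline_m=m0, baseline_h=h0,
            coverage=CoverageModel(coverage), sample_effect_sd=sample_sd,
            seed=seed * 999_983 + rep,
        )
        cohort = _paired_cohort(truth)
        prof = {}
        for signal in ("5mC", "5hmC"):
            means = region_sample_means(
                [("chr1", s, e) for s, e in intervals], cohort, signal
            )
            prof[signal] = (
                means[design.case_samples].mean(axis=1)
                - means[design.control_samples].mean(axis=1)
            )
        r, _ = profile_correlation(prof["5mC"], prof["5hmC"])
        negatives += r < 0
    return negatives / n_reps
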