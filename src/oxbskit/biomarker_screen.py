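"""Univariate DMR biomarker screening and signal-comparison analyses.

Every candidate region is scored as a one-feature classifier of group
membership using the rank-based AUC (probability a random case sample's
region mean exceeds a random control's, mid-rank ties counted half).  The
screen keeps significant DMRs with AUC above a cutoff (0.8 by default).

Two comparison analyses accompany the screen:

* ``compare_signals`` scores the same region on 5mC, 5hmC and the combined
  BS signal side by side — when 5mC and 5hmC shifts oppose each other,
  their sum partially cancels and the BS AUC is attenuated relative to the
  pure 5mC AUC;
* ``profile_correlation`` correlates two region-level difference profiles,
  used both for contrast-vs-contrast mimicry and for the global
  delta-5mC vs delta-5hmC anti-correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata, spearmanr

from .dmr_calling import DMR, build_signal_matrix, region_means_from_matrix
from .meth_io import ContrastDesign

SIGNALS = ("5mC", "5hmC", "BS")


@dataclass
class BiomarkerEval:
    region_id: str
    chrom: str
    start: int
    end: int
    signal: str
    auc: float
    mean_diff: float
    q: float
    n_samples: int
    passes_screen: bool


def auc(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Rank-based AUC: U / (n_case * n_control) with mid-rank ties.

    Equals the probability that a random case value exceeds a random
    control value, ties counting one half — the Mann-Whitney U statistic
    normalised by the number of pairs.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    case = case[~np.isnan(case)]
    control = control[~np.isnan(control)]
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([case, control]))
    u = ranks[: len(case)].sum() - len(case) * (len(case) + 1) / 2
    return float(u / (len(case) * len(control)))


def region_sample_means(
    regions: Sequence[DMR] | Sequence[tuple[str, int, int]],
    cohort: dict[str, pd.DataFrame],
    signal: str,
    min_cpgs: int = 1,
    hmc_mode: str = "raw",
) -> pd.DataFrame:
    """Region x sample matrix of mean signal over each region's CpGs.

    An entry is NaN when the sample covers fewer than ``min_cpgs`` CpGs in
    that region; regions with no covered CpGs in any sample are dropped
    with a warning.  Region ids are "chrom:start-end" (0-based half-open).
    """
    matrix = build_signal_matrix(cohort, signal, hmc_mode)
    chroms = matrix.index.get_level_values(0).to_numpy()
    positions = matrix.index.get_level_values(1).to_numpy()
    rows = {}
    dropped = 0
    for region in regions:
        chrom, start, end = (
            region.interval if isinstance(region, DMR) else region
        )
        mask = (chroms == chrom) & (positions >= start) & (positions < end)
        idx = np.flatnonzero(mask)
        rid = f"{chrom}:{start}-{end}"
        if idx.size == 0:
            dropped += 1
            continue
        block = matrix.iloc[idx]
        counts = block.notna().sum(axis=0)
        means = block.mean(axis=0, skipna=True)
        means[counts < min_cpgs] = np.nan
        rows[rid] = means
    if dropped:
        warnings.warn(f"{dropped} regions with no covered CpGs dropped")
    return pd.DataFrame(rows).T


def screen_biomarkers(
    dmrs: Sequence[DMR],
    cohort: dict[str, pd.DataFrame],
    design: ContrastDesign,
    signal: str,
    auc_cutoff: float = 0.8,
    min_sample_frac: float = 0.8,
    hmc_mode: str = "raw",
) -> list[BiomarkerEval]:
    """Evaluate each DMR as a univariate classifier; sort by AUC descending.

    The reported AUC is oriented by the marker's direction (a hypomethylated
    marker classifies by *lower* values, so its raw case-vs-control AUC of
    a is reported as 1 - a), matching how univariate biomarker AUCs are
    conventionally quoted.  A region passes the screen when it is a
    significant DMR and its oriented AUC exceeds ``auc_cutoff``.  Regions
    where fewer than ``min_sample_frac`` of contrast samples have values
    are skipped.
    """
    if not dmrs:
        return []
    means = region_sample_means(dmrs, cohort, signal, hmc_mode=hmc_mode)
    n_total = len(design.case_samples) + len(design.control_samples)
    evals: list[BiomarkerEval] = []
    for d in dmrs:
        rid = f"{d.chrom}:{d.start}-{d.end}"
        if rid not in means.index:
            continue
        row = means.loc[rid]
        case_vals = row.reindex(design.case_samples).dropna()
        control_vals = row.reindex(design.control_samples).dropna()
        n_obs = len(case_vals) + len(control_vals)
        if n_obs < min_sample_frac * n_total or not len(case_vals) or not len(control_vals):
            continue
        a = auc(case_vals, control_vals)
        mean_diff = float(case_vals.mean() - control_vals.mean())
        oriented = a if mean_diff >= 0 else 1.0 - a
        evals.append(
            BiomarkerEval(
                region_id=rid,
                chrom=d.chrom,
                start=d.start,
                end=d.end,
                signal=signal,
                auc=oriented,
                mean_diff=mean_diff,
                q=d.q,
                n_samples=n_obs,
                passes_screen=bool(oriented > auc_cutoff and d.significant),
            )
        )
    evals.sort(key=lambda e: e.auc, reverse=True)
    return evals


def compare_signals(
    region: DMR | tuple[str, int, int],
    cohort: dict[str, pd.DataFrame],
    design: ContrastDesign,
    hmc_mode: str = "raw",
) -> pd.DataFrame:
    """AUC and mean difference of one region on 5mC, 5hmC and BS.

    The BS value per sample is the plain bisulfite ratio, i.e. the sum of
    the 5mC and (raw) 5hmC components, so an opposing 5hmC shift partially
    cancels the 5mC shift in this row.
    """
    rows = []
    for signal in SIGNALS:
        means = region_sample_means([region], cohort, signal, hmc_mode=hmc_mode)
        if means.empty:
            raise ValueError("region has no covered CpGs in any sample")
        row = means.iloc[0]
        case_vals = row.reindex(design.case_samples).dropna()
        control_vals = row.reindex(design.control_samples).dropna()
        rows.append(
            {
                "signal": signal,
                "auc": auc(case_vals, control_vals),
                "mean_diff": float(case_vals.mean() - control_vals.mean()),
                "n_case": len(case_vals),
                "n_control": len(control_vals),
            }
        )
    return pd.DataFrame(rows).set_index("signal")


def profile_correlation(
    profile_a: pd.Series, profile_b: pd.Series, method: str = "pearson"
) -> tuple[float, float]:
    """Correlate two region-level difference profiles over shared regions."""
    shared = profile_a.index.intersection(profile_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared regions")
    a = profile_a.loc[shared].to_numpy(dtype=float)
    b = profile_b.loc[shared].to_numpy(dtype=float)
    if method == "pearson":
        r, p = pearsonr(a, b)
    elif method == "spearman":
        r, p = spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def differential_profile(dmrs: Sequence[DMR]) -> pd.Series:
    """Per-region mean-difference vector keyed by region id."""
    return pd.Series(
        {f"{d.chrom}:{d.start}-{d.end}": d.mean_diff for d in dmrs}, dtype=float
    )


def evals_to_frame(evals: Sequence[BiomarkerEval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": e.region_id,
                "signal": e.signal,
                "auc": e.auc,
                "mean_diff": e.mean_diff,
                "q": e.q,
                "n_samples": e.n_samples,
                "passes_screen": e.passes_screen,
            }
            for e in evals
        ]
    )
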