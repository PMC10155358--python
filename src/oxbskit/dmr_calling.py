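"""De-novo DMR calling between two groups on any of the three signals.

Signals: 5mC (oxBS ratio), 5hmC (BS - oxBS subtraction estimate) and BS
(the plain bisulfite ratio, i.e. 5mC + 5hmC combined).

Procedure per (contrast, mark):

1. assemble a site x sample signal matrix; retain sites covered in at
   least ``min_group_presence`` of the samples of each group;
2. group retained CpGs into runs with inter-CpG gaps <= ``max_gap`` bp,
   then recursively binary-split each run at the breakpoint that maximises
   the contrast between child mean group differences, while each child
   keeps >= ``min_cpg`` CpGs and splitting raises the best child
   |mean difference| by at least ``split_gain``;
3. test each candidate with a two-sided Mann-Whitney U on per-sample
   region means (samples, not CpGs, are the replication unit); the exact
   permutation distribution is used for small cohorts, a tie-corrected
   normal approximation with continuity correction otherwise;
4. Benjamini-Hochberg adjust across all candidates of the family, then
   flag regions with q < 0.05 and |mean difference| above the mark-specific
   effect threshold (0.2 for 5mC and BS, 0.1 for 5hmC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .meth_io import ContrastDesign

MARKS = ("5mC", "5hmC", "BS")

DEFAULT_DIFF_THRESHOLDS = {"5mC": 0.2, "BS": 0.2, "5hmC": 0.1}
DEFAULT_Q_THRESHOLD = 0.05
EXACT_LIMIT = 12  # exact MWU distribution up to this pooled sample size


@dataclass
class SegmentationParams:
    max_gap: int = 300          # bp between consecutive CpGs within a run
    min_cpg: int = 5            # minimum CpGs per candidate region
    min_group_presence: float = 0.8
    split_gain: float = 0.05    # required gain in child |mean diff|


@dataclass
class Thresholds:
    diff: dict = field(default_factory=lambda: dict(DEFAULT_DIFF_THRESHOLDS))
    q: float = DEFAULT_Q_THRESHOLD


@dataclass
class DMR:
    """A called region: 0-based half-open interval plus test results."""

    chrom: str
    start: int
    end: int
    mark: str
    n_cpgs: int
    mean_case: float
    mean_control: float
    mean_diff: float
    p: float
    q: float = float("nan")
    significant: bool = False

    @property
    def direction(self) -> str:
        return "hyper" if self.mean_diff > 0 else "hypo"

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def signal_values(paired: pd.DataFrame, signal: str, hmc_mode: str = "raw") -> pd.Series:
    """Extract one signal from a paired-site table, indexed by (chrom, pos)."""
    if signal == "5mC":
        v = paired["beta_ox"]
    elif signal == "BS":
        v = paired["beta_bs"]
    elif signal == "5hmC":
        v = paired["beta_bs"] - paired["beta_ox"]
        if hmc_mode == "clamp":
            v = v.clip(lower=0.0)
        elif hmc_mode != "raw":
            raise ValueError(f"unknown 5hmC mode {hmc_mode!r}")
    else:
        raise ValueError(f"unknown signal {signal!r}; expected one of {MARKS}")
    return pd.Series(
        v.to_numpy(), index=pd.MultiIndex.from_frame(paired[["chrom", "pos"]])
    )


def build_signal_matrix(
    cohort: dict[str, pd.DataFrame], signal: str, hmc_mode: str = "raw"
) -> pd.DataFrame:
    """Site x sample matrix of one signal; NaN where a sample lacks the site."""
    series = {s: signal_values(t, signal, hmc_mode) for s, t in cohort.items()}
    matrix = pd.DataFrame(series)
    return matrix.sort_index()


def segment_candidates(
    positions: np.ndarray,
    diffs: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> list[tuple[int, int]]:
    """Candidate regions as (start_idx, end_idx) half-open index slices.

    ``positions`` must be sorted; ``diffs`` is the per-CpG group mean
    difference used to steer the recursive splitting.
    """
    positions = np.asarray(positions)
    diffs = np.asarray(diffs, dtype=float)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    out: list[tuple[int, int]] = []
    breaks = np.flatnonzero(np.diff(positions) > params.max_gap)
    run_edges = np.concatenate([[0], breaks + 1, [len(positions)]])
    csum = np.concatenate([[0.0], np.cumsum(diffs)])

    def mean(i: int, j: int) -> float:
        return (csum[j] - csum[i]) / (j - i)

    def split(i: int, j: int) -> None:
        n = j - i
        if n < params.min_cpg:
            return
        if n < 2 * params.min_cpg:
            out.append((i, j))
            return
        parent = abs(mean(i, j))
        ks = np.arange(i + params.min_cpg, j - params.min_cpg + 1)
        left = (csum[ks] - csum[i]) / (ks - i)
        right = (csum[j] - csum[ks]) / (j - ks)
        scores = np.abs(left - right)
        k = int(ks[np.argmax(scores)])
        child_best = max(abs(mean(i, k)), abs(mean(k, j)))
        if child_best >= parent + params.split_gain:
            split(i, k)
            split(k, j)
        else:
            out.append((i, j))

    for a, b in zip(run_edges[:-1], run_edges[1:]):
        split(int(a), int(b))
    return out


def _u_statistic(case: np.ndarray, control: np.ndarray) -> float:
    """Mann-Whitney U for the case group, mid-rank ties."""
    pooled = np.concatenate([case, control])
    ranks = rankdata(pooled)
    return float(ranks[: len(case)].sum() - len(case) * (len(case) + 1) / 2)


def mann_whitney_exact_p(case: np.ndarray, control: np.ndarray) -> float:
    """Exact two-sided p by complete enumeration of group assignments.

    Enumerates all C(n1+n2, n1) ways of assigning the pooled mid-ranks to
    the case group and reports the fraction with |U - n1*n2/2| at least as
    large as observed.  Correct under ties, unlike the classical
    no-ties recursion.
    """
    n1, n2 = len(case), len(control)
    pooled = np.concatenate([case, control])
    ranks = rankdata(pooled)
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    stat_obs = abs(u_obs - mu)
    hits = 0
    offset = n1 * (n1 + 1) / 2
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= stat_obs - 1e-9:
            hits += 1
    return hits / comb(n1 + n2, n1)


def mann_whitney_normal_p(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided normal approximation with tie correction and continuity."""
    n1, n2 = len(case), len(control)
    pooled = np.concatenate([case, control])
    n = n1 + n2
    u = _u_statistic(case, control)
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0  # all values tied
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


def test_region(
    case_values: Sequence[float],
    control_values: Sequence[float],
    exact_limit: int = EXACT_LIMIT,
) -> tuple[float, float]:
    """Two-group region test: (mean difference, two-sided MWU p).

    Exact permutation distribution when the pooled sample size is at most
    ``exact_limit``, tie-corrected normal approximation with continuity
    correction otherwise.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least two samples per group")
    mean_diff = float(case.mean() - control.mean())
    if len(case) + len(control) <= exact_limit:
        p = mann_whitney_exact_p(case, control)
    else:
        p = mann_whitney_normal_p(case, control)
    return mean_diff, p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j over the ascending order statistics,
    capped at 1.  Empty input yields an empty array.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def region_means_from_matrix(
    matrix: pd.DataFrame, idx: tuple[int, int], min_cpgs: int = 1
) -> pd.Series:
    """Per-sample means over rows [idx) of a site x sample matrix."""
    block = matrix.iloc[idx[0]: idx[1]]
    counts = block.notna().sum(axis=0)
    means = block.mean(axis=0, skipna=True)
    means[counts < min_cpgs] = np.nan
    return means


def call_dmrs(
    cohort: dict[str, pd.DataFrame],
    design: ContrastDesign,
    mark: str,
    thresholds: Thresholds | None = None,
    seg: SegmentationParams | None = None,
    hmc_mode: str = "raw",
) -> list[DMR]:
    """Segment, test, BH-adjust and flag DMRs for one contrast and mark.

    ``cohort`` maps sample id -> merged paired-site table.  Every DMR
    candidate is returned (so families can be audited); ``significant``
    marks those passing both the q and the effect-size gate.
    """
    thresholds = thresholds or Thresholds()
    seg = seg or SegmentationParams()
    case_ids = [s for s in design.case_samples if s in cohort]
    control_ids = [s for s in design.control_samples if s in cohort]
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError(f"contrast {design.name!r}: need >=2 samples per group")
    matrix = build_signal_matrix(
        {s: cohort[s] for s in case_ids + control_ids}, mark, hmc_mode
    )
    present_case = matrix[case_ids].notna().mean(axis=1) >= seg.min_group_presence
    present_control = (
        matrix[control_ids].notna().mean(axis=1) >= seg.min_group_presence
    )
    matrix = matrix[present_case & present_control]
    if matrix.empty:
        return []
    diffs = (
        matrix[case_ids].mean(axis=1, skipna=True)
        - matrix[control_ids].mean(axis=1, skipna=True)
    )
    dmrs: list[DMR] = []
    for chrom in matrix.index.get_level_values(0).unique():
        sub = matrix.loc[chrom]
        sub_diffs = diffs.loc[chrom].to_numpy()
        positions = sub.index.to_numpy()
        for i, j in segment_candidates(positions, sub_diffs, seg):
            means = region_means_from_matrix(sub, (i, j))
            case_vals = means[case_ids].dropna()
            control_vals = means[control_ids].dropna()
            if len(case_vals) < 2 or len(control_vals) < 2:
                continue
            mean_diff, p = test_region(case_vals, control_vals)
            dmrs.append(
                DMR(
                    chrom=str(chrom),
                    start=int(positions[i]),
                    end=int(positions[j - 1]) + 2,  # CpG dyad spans 2 bp
                    mark=mark,
                    n_cpgs=j - i,
                    mean_case=float(case_vals.mean()),
                    mean_control=float(control_vals.mean()),
                    mean_diff=mean_diff,
                    p=p,
                )
            )
    if dmrs:
        q = bh_adjust([d.p for d in dmrs])
        gate = thresholds.diff[mark]
        for d, qi in zip(dmrs, q):
            d.q = float(qi)
            d.significant = bool(qi < thresholds.q and abs(d.mean_diff) > gate)
    return dmrs


def significant_dmrs(dmrs: Sequence[DMR]) -> list[DMR]:
    return [d for d in dmrs if d.significant]
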