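"""Per-CpG 5mC / 5hmC estimation from paired BS/oxBS calls.

The BS (plain bisulfite) ratio measures 5mC + 5hmC; the oxBS ratio measures
5mC alone.  The subtraction estimator is therefore

    h_hat = beta_BS - beta_oxBS,      m_hat = beta_oxBS.

Three modes are offered:

raw    the plain subtraction; unbiased but h_hat may be negative at low
       coverage.  Default for group-difference and correlation work.
clamp  projects onto [0, 1]: h_hat = max(0, beta_BS - beta_oxBS),
       m_hat = min(beta_oxBS, beta_BS).  Used when reporting per-sample
       levels.
mle    constrained maximum likelihood of the two binomials
       c_BS ~ Bin(n_BS, m + h), c_oxBS ~ Bin(n_oxBS, m) over the simplex
       {m, h >= 0, m + h <= 1}.  Solved in closed form: the likelihood is
       separable in t = m + h and m, so when beta_oxBS <= beta_BS the
       interior optimum (m, h) = (beta_oxBS, beta_BS - beta_oxBS) applies;
       otherwise the optimum sits on the boundary h = 0 with the pooled
       estimate m = (c_BS + c_oxBS) / (n_BS + n_oxBS).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAIRED_COLUMNS = [
    "chrom", "pos", "beta_bs", "beta_ox", "cov_bs", "cov_ox", "c_bs", "c_ox",
]
DEFAULT_MIN_COV = 5
MODES = ("raw", "clamp", "mle")


def merge_paired(
    bs_table: pd.DataFrame, ox_table: pd.DataFrame, min_cov: int = DEFAULT_MIN_COV
) -> pd.DataFrame:
    """Inner-join a sample's BS and oxBS site tables on (chrom, pos).

    Sites below ``min_cov`` in either library are dropped; drop counts are
    logged.  A disjoint pair of tables yields an empty result with a
    warning.
    """
    merged = bs_table.merge(
        ox_table, on=["chrom", "pos"], suffixes=("_bs", "_ox"), how="inner"
    )
    n_joined = len(merged)
    if n_joined == 0:
        warnings.warn("BS and oxBS tables share no sites")
    merged = merged.rename(
        columns={
            "ratio_bs": "beta_bs",
            "ratio_ox": "beta_ox",
            "ct_count_bs": "cov_bs",
            "ct_count_ox": "cov_ox",
            "c_count_bs": "c_bs",
            "c_count_ox": "c_ox",
        }
    )
    keep = (merged["cov_bs"] >= min_cov) & (merged["cov_ox"] >= min_cov)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("merge_paired: dropped %d/%d sites below min_cov=%d",
                    n_dropped, n_joined, min_cov)
    return merged.loc[keep, PAIRED_COLUMNS].reset_index(drop=True)


def estimate_hmc(paired: pd.DataFrame, mode: str = "raw") -> pd.DataFrame:
    """Fill h_hat and m_hat columns of a merged paired-site table."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    out = paired.copy()
    bb = out["beta_bs"].to_numpy(dtype=float)
    bo = out["beta_ox"].to_numpy(dtype=float)
    if mode == "raw":
        m_hat, h_hat = bo, bb - bo
    elif mode == "clamp":
        h_hat = np.maximum(0.0, bb - bo)
        m_hat = np.minimum(bo, bb)
    else:
        m_hat, h_hat = _mle(
            out["c_bs"].to_numpy(), out["cov_bs"].to_numpy(),
            out["c_ox"].to_numpy(), out["cov_ox"].to_numpy(),
        )
    out["m_hat"] = m_hat
    out["h_hat"] = h_hat
    return out


def _mle(c_bs, n_bs, c_ox, n_ox):
    """Closed-form constrained binomial MLE on the 2-simplex (vectorised)."""
    beta_bs = c_bs / n_bs
    beta_ox = c_ox / n_ox
    interior = beta_ox <= beta_bs
    m = np.where(interior, beta_ox, (c_bs + c_ox) / (n_bs + n_ox))
    h = np.where(interior, beta_bs - beta_ox, 0.0)
    return m, h


def write_paired_table(paired: pd.DataFrame, path) -> None:
    cols = ["chrom", "pos", "beta_bs", "beta_ox", "h_hat", "m_hat", "cov_bs", "cov_ox"]
    paired[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_paired_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
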