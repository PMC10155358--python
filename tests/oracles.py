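"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the code paths they check: the MLE oracle is an
exhaustive lattice search of the likelihood, the Mann-Whitney oracle
enumerates raw group assignments and counts pairs directly, the AUC oracle
counts pairs, and the BH oracle is statsmodels' implementation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import binom


def lattice_mle(c_bs, n_bs, c_ox, n_ox, step=0.001):
    """Exhaustive search of the constrained likelihood on a lattice.

    Maximises Binom(c_bs; n_bs, m+h) * Binom(c_ox; n_ox, m) over the grid
    {(m, h): m, h in {0, step, ...}, m + h <= 1} by scanning all (m, t)
    pairs with t = m + h >= m.
    """
    grid = np.arange(0.0, 1.0 + step / 2, step)
    ll_m = binom.logpmf(c_ox, n_ox, grid)
    ll_t = binom.logpmf(c_bs, n_bs, grid)
    total = ll_m[:, None] + ll_t[None, :]  # (m index, t index)
    total[np.tril_indices_from(total, k=-1)] = -np.inf  # enforce m <= t
    i, j = np.unravel_index(np.argmax(total), total.shape)
    m = grid[i]
    t = grid[j]
    return float(m), float(t - m)


def permutation_mwu_p(case, control):
    """Two-sided Mann-Whitney p by enumerating raw value assignments.

    For every way of labelling n_case of the pooled values as cases, the
    U statistic is computed by direct pair counting (ties count half); the
    p-value is the fraction of labellings whose |U - n1*n2/2| reaches the
    observed one.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    pooled = np.concatenate([case, control])
    n1, n2 = len(case), len(control)
    mu = n1 * n2 / 2.0

    def u_of(idx):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        a, b = pooled[sel], pooled[~sel]
        gt = (a[:, None] > b[None, :]).sum()
        eq = (a[:, None] == b[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_of(range(n1))
    stat_obs = abs(u_obs - mu)
    hits = sum(
        abs(u_of(idx) - mu) >= stat_obs - 1e-9
        for idx in combinations(range(n1 + n2), n1)
    )
    return hits / comb(n1 + n2, n1)


def pair_count_auc(case, control):
    """AUC by direct enumeration of all (case, control) pairs."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    wins = (case[:, None] > control[None, :]).sum()
    ties = (case[:, None] == control[None, :]).sum()
    return (wins + 0.5 * ties) / (len(case) * len(control))


def reference_bh(pvalues):
    """Benjamini-Hochberg via statsmodels, as an independent reference."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues), method="fdr_bh")[1]
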