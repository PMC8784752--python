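"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (loops, enumeration, O(n^2) scans,
exact rational arithmetic) and shares no code with the package internals.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def naive_breslow_loglik(eta, time, event) -> float:
    """O(n^2) Breslow log partial likelihood for a fixed linear predictor."""
    eta = np.asarray(eta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = time >= time[i]
            ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll


def grid_cox_beta(x, time, event, lo=-5.0, hi=5.0, passes=4, points=201) -> float:
    """Single-covariate Cox beta by iterative grid refinement of the
    naive partial likelihood (resolution ~ (hi-lo) / points**passes)."""
    x = np.asarray(x, dtype=float)
    for _ in range(passes):
        grid = np.linspace(lo, hi, points)
        lls = [naive_breslow_loglik(b * x, time, event) for b in grid]
        k = int(np.argmax(lls))
        step = grid[1] - grid[0]
        lo, hi = grid[k] - step, grid[k] + step
    return float((lo + hi) / 2)


def brute_pair_filter(X: np.ndarray, gene_ids, low=Fraction(1, 5),
                      high=Fraction(4, 5)) -> set[str]:
    """Retained pair labels by exact count-of-ones rational comparison."""
    order = np.argsort(gene_ids)
    n = X.shape[1]
    kept = set()
    for ii in range(len(gene_ids)):
        for jj in range(ii + 1, len(gene_ids)):
            a, b = order[ii], order[jj]
            ones = sum(int(X[a, s] > X[b, s]) for s in range(n))
            if low <= Fraction(ones, n) <= high:
                kept.add(f"{gene_ids[a]}|{gene_ids[b]}")
    return kept


def mann_whitney_auc(risk, case_mask) -> float:
    """Pairwise-comparison AUC (ties count 1/2)."""
    risk = np.asarray(risk, dtype=float)
    cases = risk[np.asarray(case_mask, bool)]
    controls = risk[~np.asarray(case_mask, bool)]
    total = 0.0
    for c in cases:
        for d in controls:
            total += (c > d) + 0.5 * (c == d)
    return total / (len(cases) * len(controls))


def logrank_chi2(time, event, mask_a) -> float:
    """Two-group log-rank chi-square by direct O-E / hypergeometric sums."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    mask_a = np.asarray(mask_a, bool)
    num, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & mask_a).sum()
        d = ((time == t) & (event == 1)).sum()
        d_a = ((time == t) & (event == 1) & mask_a).sum()
        num += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return num ** 2 / var


def permutation_pvalue(statistic_fn, labels, n_perm, rng, observed) -> float:
    """Two-sided permutation p for a label-exchange statistic."""
    labels = np.asarray(labels)
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if statistic_fn(perm) >= observed - 1e-12:
            count += 1
    return count / (n_perm + 1)


def chi2_pearson(table: np.ndarray) -> float:
    """Direct sum (O-E)^2/E over a contingency table."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
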