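"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's interval/statistics code paths:
intervals are checked against per-base boolean occupancy arrays, Fisher
p-values against exact integer-arithmetic enumeration, rank-sum p-values
against full combinatorial enumeration, and correlations against per-pair
scipy.stats.pearsonr calls.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats


def per_base_mask(intervals, size: int) -> np.ndarray:
    mask = np.zeros(size, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def brute_union_length(intervals, size: int) -> int:
    return int(per_base_mask(intervals, size).sum())


def brute_covered_bp(query, subjects, size: int) -> int:
    qmask = per_base_mask([query], size)
    smask = per_base_mask(subjects, size)
    return int((qmask & smask).sum())


def fisher_enum_p(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact integer arithmetic."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    weights = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    total = comb(n, c1)
    obs = weights[a]
    p = Fraction(sum(w for w in weights.values() if w <= obs), total)
    return float(min(Fraction(1), p))


def exact_rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = np.asarray(x + y, dtype=float)
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def brute_force_edges(matrix, pseudo_ids, coding_ids, r_cut=0.90, p_cut=0.01):
    """All-pairs co-expression edges via per-pair scipy.stats.pearsonr."""
    edges = set()
    for p in pseudo_ids:
        for c in coding_ids:
            x = matrix.loc[p].to_numpy(dtype=float)
            y = matrix.loc[c].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                continue
            r, pval = stats.pearsonr(x, y)
            if abs(r) > r_cut and pval < p_cut:
                edges.add((p, c))
    return edges


def nch_expectation(table, psi: float) -> float:
    """Mean of Fisher's noncentral hypergeometric for the table's margins."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logw = (
        np.array([np.log(comb(r1, k)) + np.log(comb(n - r1, c1 - k)) for k in ks])
        + ks * np.log(psi)
    )
    w = np.exp(logw - logw.max())
    return float((ks * w).sum() / w.sum())
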