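"""Independent brute-force oracles used by the test suite.

Everything here is deliberately re-derived from first principles (literal set
operations, explicit rank arithmetic) and stays independent of the package
code paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def masked_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r² over complete pairs; NaN when monomorphic or < 2 pairs."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return float("nan")
    sx = x - x.mean()
    sy = y - y.mean()
    den = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if den == 0.0:
        return float("nan")
    r = float(sx @ sy) / den
    return r * r


def greedy_clump_oracle(
    ids: list[str],
    positions: list[int],
    pvalues: list[float],
    dosages: np.ndarray,
    p_threshold: float,
    r2_threshold: float,
    window_bp: float,
) -> tuple[list[str], dict[str, list[str]]]:
    """Literal re-statement of the greedy clumping rule.

    Candidates are variants with p <= p_threshold; repeatedly the candidate
    with the smallest (p, pos, id) becomes an index and absorbs every other
    unassigned candidate within the window whose r² with it reaches the
    threshold (undefined r² counts as 0).
    """
    unassigned = {
        i for i in range(len(ids)) if pvalues[i] <= p_threshold
    }
    index_order: list[str] = []
    members: dict[str, list[str]] = {}
    while unassigned:
        best = min(unassigned, key=lambda i: (pvalues[i], positions[i], ids[i]))
        unassigned.discard(best)
        absorbed = []
        for j in sorted(unassigned):
            if abs(positions[j] - positions[best]) > window_bp:
                continue
            r2 = masked_r2(dosages[:, best], dosages[:, j])
            if not math.isnan(r2) and r2 >= r2_threshold:
                absorbed.append(j)
        for j in absorbed:
            unassigned.discard(j)
        index_order.append(ids[best])
        members[ids[best]] = [ids[j] for j in absorbed]
    return index_order, members


def _midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks computed by explicit sorting (no scipy)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def _tie_sum(values: np.ndarray) -> float:
    out = 0.0
    for v in set(values.tolist()):
        t = int((values == v).sum())
        out += t**3 - t
    return out


def kruskal_oracle(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p, from the definition."""
    from scipy.stats import chi2

    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    corr = 1.0 - _tie_sum(pooled) / (n**3 - n)
    if corr <= 0:
        return 0.0, 1.0
    h /= corr
    return h, float(chi2.sf(h, len(groups) - 1))


def dunn_oracle(groups: list[np.ndarray]) -> dict[tuple[int, int], tuple[float, float]]:
    """Dunn z and two-sided normal p per pair index, from the definition."""
    from scipy.stats import norm

    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = _midranks(pooled)
    mean_rank = []
    start = 0
    for g in groups:
        mean_rank.append(ranks[start : start + g.size].mean())
        start += g.size
    var_term = n * (n + 1) / 12.0 - _tie_sum(pooled) / (12.0 * (n - 1))
    out = {}
    for a, b in combinations(range(len(groups)), 2):
        den2 = var_term * (1.0 / groups[a].size + 1.0 / groups[b].size)
        if den2 <= 0:
            out[(a, b)] = (0.0, 1.0)
            continue
        z = (mean_rank[a] - mean_rank[b]) / math.sqrt(den2)
        out[(a, b)] = (z, float(2.0 * norm.sf(abs(z))))
    return out


def score_oracle(
    dosages: np.ndarray, betas: np.ndarray, impute_means: np.ndarray | None = None
) -> np.ndarray:
    """Double-loop weighted allele sum with mean imputation."""
    n, m = dosages.shape
    if impute_means is None:
        impute_means = np.nanmean(dosages, axis=0)
    out = np.zeros(n)
    for i in range(n):
        for j in range(m):
            d = dosages[i, j]
            if np.isnan(d):
                d = impute_means[j]
            out[i] += betas[j] * d
    return out
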