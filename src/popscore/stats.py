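"""Rank-based group comparisons of score distributions.

Kruskal–Wallis across groups per tissue (tie-corrected H referred to a
chi-square with k-1 degrees of freedom), Dunn's z for pairwise post-hoc
contrasts on pooled mid-ranks, Bonferroni correction over the tissues tested.
Dunn pairwise p-values are additionally Bonferroni-adjusted across the pairs
within a tissue; both nominal and adjusted values are reported.

The Dunn z sign convention is first group minus second group (mean ranks),
with groups taken in panel order, so z(A, B) = -z(B, A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .io import SamplePanel
from .scoring import ScoreMatrix

#: Smallest positive double; p-values are clamped into (0, 1].
_TINY = np.nextafter(0.0, 1.0)


@dataclass
class KWResult:
    tissue: str
    level: str  # "ancestry" or "population"
    group: str | None  # ancestry group for within-perspective rows
    H: float
    df: int
    p_nominal: float
    p_bonferroni: float


@dataclass
class DunnResult:
    tissue: str
    group: str | None
    pair: tuple[str, str]
    z: float
    p_nominal: float
    p_adjusted: float


@dataclass
class ComparisonReport:
    perspective: str
    kw: pd.DataFrame
    dunn: pd.DataFrame


def _tie_term(ranks_source: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(ranks_source, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(values: Sequence[float], labels: Sequence[str]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H, degrees of freedom and chi-square p.

    With every pooled value tied the statistic is degenerate; (0, k-1, 1.0) is
    returned by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    k = len(groups)
    if k < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    n = values.size
    ranks = rankdata(values)
    h = 0.0
    for g in groups:
        r = ranks[labels == g]
        if r.size == 0:
            raise ValueError(f"group {g!r} has no observation")
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(values) / (n**3 - n)
    if correction <= 0:  # all pooled values tied
        return 0.0, k - 1, 1.0
    h /= correction
    h = max(h, 0.0)
    p = float(min(max(chi2.sf(h, k - 1), _TINY), 1.0))
    return float(h), k - 1, p


def dunn_posthoc(
    values: Sequence[float],
    labels: Sequence[str],
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dunn's pairwise post-hoc z and two-sided p for every unordered pair.

    z(A, B) = (meanrank_A - meanrank_B) / sqrt(
        [N(N+1)/12 - sum(t^3 - t)/(12(N-1))] * (1/n_A + 1/n_B))
    over pooled mid-ranks.  ``p_adjusted`` is Bonferroni over the pairs in
    this call.  When every pooled value is tied, z = 0 and p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if group_order is None:
        group_order = list(dict.fromkeys(labels))
    k = len(group_order)
    if k < 2:
        raise ValueError("dunn_posthoc requires >= 2 groups")
    n = values.size
    ranks = rankdata(values)
    mean_rank = {}
    size = {}
    for g in group_order:
        r = ranks[labels == g]
        if r.size == 0:
            raise ValueError(f"group {g!r} has no observation")
        mean_rank[g] = r.mean()
        size[g] = r.size
    var_term = n * (n + 1) / 12.0 - _tie_term(values) / (12.0 * (n - 1))
    n_pairs = k * (k - 1) // 2
    rows = []
    for a, b in combinations(group_order, 2):
        denom2 = var_term * (1.0 / size[a] + 1.0 / size[b])
        if denom2 <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(denom2)
            p = float(min(max(2.0 * norm.sf(abs(z)), _TINY), 1.0))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": size[a],
                "n_b": size[b],
                "z": float(z),
                "p_nominal": p,
                "p_adjusted": float(min(1.0, p * n_pairs)),
            }
        )
    return pd.DataFrame(rows)


def _compare_one_matrix(
    scores: ScoreMatrix,
    labels: Sequence[str],
    level: str,
    group: str | None,
    n_tissues: int,
    label_order: Sequence[str],
) -> tuple[list[dict], list[dict]]:
    kw_rows, dunn_rows = [], []
    for t_idx, tissue in enumerate(scores.tissues):
        vals = scores.scores[:, t_idx]
        h, df, p = kruskal_wallis(vals, labels)
        kw_rows.append(
            {
                "tissue": tissue,
                "level": level,
                "group": group if group is not None else "",
                "n_groups": df + 1,
                "H": h,
                "df": df,
                "p_nominal": p,
                "p_bonferroni": float(min(1.0, p * n_tissues)),
            }
        )
        dn = dunn_posthoc(vals, labels, group_order=label_order)
        for row in dn.itertuples(index=False):
            dunn_rows.append(
                {
                    "tissue": tissue,
                    "group": group if group is not None else "",
                    "group_a": row.group_a,
                    "group_b": row.group_b,
                    "n_a": row.n_a,
                    "n_b": row.n_b,
                    "z": row.z,
                    "p_nominal": row.p_nominal,
                    "p_adjusted": row.p_adjusted,
                }
            )
    return kw_rows, dunn_rows


def run_comparisons(
    scores: ScoreMatrix | Sequence[ScoreMatrix],
    panel: SamplePanel,
    perspective: str = "among",
) -> ComparisonReport:
    """Kruskal–Wallis + Dunn over ancestry groups (among) or over populations
    within each ancestry group (within).

    ``among`` takes a single all-sample :class:`ScoreMatrix`; ``within`` takes
    the per-group matrices (each scored from that group's own clumped variant
    sets).  Kruskal–Wallis p-values are Bonferroni-corrected over the tissues
    tested; a within-group with fewer than two populations is skipped with a
    warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    if perspective not in ("among", "within"):
        raise ValueError(f"unknown perspective {perspective!r}")

    kw_rows: list[dict] = []
    dunn_rows: list[dict] = []
    if perspective == "among":
        if not isinstance(scores, ScoreMatrix):
            raise TypeError("among-perspective expects a single ScoreMatrix")
        labels = panel.labels_for(scores.sample_ids, "ancestry")
        order = [g for g in panel.groups if g in set(labels)]
        if len(order) < 2:
            logger.warning("fewer than 2 ancestry groups; among-comparison skipped")
        else:
            kw, dn = _compare_one_matrix(
                scores, labels, "ancestry", None, len(scores.tissues), order
            )
            kw_rows += kw
            dunn_rows += dn
    else:
        matrices = [scores] if isinstance(scores, ScoreMatrix) else list(scores)
        for sm in matrices:
            group = sm.group
            labels = panel.labels_for(sm.sample_ids, "population")
            pops = [p for p in panel.populations(group) if p in set(labels)]
            if len(pops) < 2:
                logger.warning("group %r has < 2 populations; skipped", group)
                continue
            kw, dn = _compare_one_matrix(
                sm, labels, "population", group, len(sm.tissues), pops
            )
            kw_rows += kw
            dunn_rows += dn

    kw_cols = ["tissue", "level", "group", "n_groups", "H", "df", "p_nominal", "p_bonferroni"]
    dunn_cols = [
        "tissue", "group", "group_a", "group_b", "n_a", "n_b", "z", "p_nominal", "p_adjusted",
    ]
    return ComparisonReport(
        perspective=perspective,
        kw=pd.DataFrame(kw_rows, columns=kw_cols),
        dunn=pd.DataFrame(dunn_rows, columns=dunn_cols),
    )
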