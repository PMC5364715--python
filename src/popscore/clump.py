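"""Greedy p-value-sorted LD clumping of a tissue's weighted variant set.

Follows the Plink ``--clump`` convention: repeatedly take the remaining
candidate with the smallest association p-value as an index variant and absorb
every remaining candidate within the distance window whose squared dosage
correlation with the index reaches the r² threshold.  A single p-value cutoff
is applied to index and absorbed variants alike.  The LD reference is a
caller-chosen sample subset: all samples for among-ancestry comparisons, one
ancestry group's samples for within-ancestry comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeRegion, SamplePanel, WeightTable

#: LD-subset label used when all samples form the reference.
ALL_SAMPLES = "ALL"


@dataclass(frozen=True)
class ClumpParams:
    """p-value cutoff, r² cutoff and distance window (kb) for clumping."""

    p_threshold: float = 0.1
    r2_threshold: float = 0.5
    window_kb: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError(f"r2_threshold must be in [0, 1], got {self.r2_threshold}")
        if self.window_kb <= 0:
            raise ValueError(f"window_kb must be > 0, got {self.window_kb}")


@dataclass
class ClumpResult:
    tissue: str
    ld_subset: str
    index_variants: list[str]
    members: dict[str, list[str]]

    @property
    def all_variants(self) -> set[str]:
        out = set(self.index_variants)
        for mem in self.members.values():
            out.update(mem)
        return out


def pairwise_r2(
    region: GenotypeRegion,
    sample_subset: Sequence[str],
    i: int,
    j: int,
) -> float:
    """Squared Pearson correlation of alt dosages at variants ``i`` and ``j``.

    Computed over subset samples with non-missing genotypes at both variants;
    returns ``NaN`` (treated as 0 by clumping) when either variant is
    monomorphic in the subset or fewer than two complete pairs exist.
    """
    if len(sample_subset) == 0:
        raise ValueError("sample subset must be non-empty")
    rows = region.sample_indices(sample_subset)
    x = region.dosages[rows, i]
    y = region.dosages[rows, j]
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def r2_matrix(region: GenotypeRegion, sample_subset: Sequence[str]) -> np.ndarray:
    """All-pairs r² over a sample subset, pairwise-complete over missing calls.

    Undefined entries (monomorphic variant, < 2 complete pairs) are ``NaN``.
    """
    if len(sample_subset) == 0:
        raise ValueError("sample subset must be non-empty")
    rows = region.sample_indices(sample_subset)
    sub = pd.DataFrame(region.dosages[rows, :])
    corr = sub.corr(min_periods=2).to_numpy()
    return corr * corr


def _candidates(weights: WeightTable, tissue: str, params: ClumpParams) -> pd.DataFrame:
    sub = weights.for_tissue(tissue)
    return sub[sub["pvalue"].astype(float) <= params.p_threshold]


def clump(
    region: GenotypeRegion,
    weights: WeightTable,
    tissue: str,
    sample_subset: Sequence[str],
    params: ClumpParams = ClumpParams(),
    *,
    ld_subset_label: str | None = None,
    r2: np.ndarray | None = None,
) -> ClumpResult:
    """Clump one tissue's candidate variants over one LD reference subset.

    Candidates are the tissue's weight rows with p <= ``p_threshold`` whose
    variant is present in the region.  Greedy order is (p, pos, id); each index
    absorbs every unassigned candidate within ±``window_kb`` whose r² with it
    reaches ``r2_threshold`` (undefined r² counts as 0).  An empty candidate
    set yields an empty result, not an error.

    ``r2`` may carry a precomputed :func:`r2_matrix` for the same subset so
    that the matrix is shared across the 14 tissues.
    """
    cand = _candidates(weights, tissue, params)
    id_to_col = {v.id: k for k, v in enumerate(region.variants)}
    entries = []
    for row in cand.itertuples(index=False):
        col = id_to_col.get(row.variant_id)
        if col is None:
            continue
        entries.append((float(row.pvalue), region.variants[col].pos, row.variant_id, col))
    entries.sort()

    label = ld_subset_label if ld_subset_label is not None else ALL_SAMPLES
    if r2 is None and entries:
        r2 = r2_matrix(region, sample_subset)

    window_bp = params.window_kb * 1000.0
    unassigned = list(entries)
    index_variants: list[str] = []
    members: dict[str, list[str]] = {}
    while unassigned:
        _, idx_pos, idx_id, idx_col = unassigned.pop(0)
        index_variants.append(idx_id)
        absorbed: list[tuple[int, str]] = []
        remaining = []
        for entry in unassigned:
            _, pos, vid, col = entry
            if abs(pos - idx_pos) <= window_bp:
                r2_val = r2[idx_col, col]
                if not np.isnan(r2_val) and r2_val >= params.r2_threshold:
                    absorbed.append((pos, vid))
                    continue
            remaining.append(entry)
        # members reported in genomic order for reproducible serialization
        members[idx_id] = [vid for _, vid in sorted(absorbed)]
        unassigned = remaining
    return ClumpResult(tissue=tissue, ld_subset=label, index_variants=index_variants, members=members)


def clump_all(
    region: GenotypeRegion,
    weights: WeightTable,
    panel: SamplePanel,
    params: ClumpParams = ClumpParams(),
    perspective: Literal["among", "within"] = "among",
) -> list[ClumpResult]:
    """Clump every tissue under one of the two analysis perspectives.

    ``among``: one LD reference (all samples), one result per tissue.
    ``within``: one LD reference per ancestry group, |tissues| x |groups|
    results (the group's samples serve as both LD reference and score cohort
    downstream).
    """
    if perspective not in ("among", "within"):
        raise ValueError(f"unknown perspective {perspective!r}")
    results: list[ClumpResult] = []
    if perspective == "among":
        subsets = [(ALL_SAMPLES, list(region.sample_ids))]
    else:
        subsets = [(g, panel.samples_in_group(g)) for g in panel.groups]
    for label, samples in subsets:
        r2 = r2_matrix(region, samples)
        for tissue in weights.tissues:
            results.append(
                clump(region, weights, tissue, samples, params, ld_subset_label=label, r2=r2)
            )
    return results


def clumps_to_frame(results: Iterable[ClumpResult]) -> pd.DataFrame:
    """Serialize clump results (one row per index variant)."""
    rows = []
    for res in results:
        for idx in res.index_variants:
            rows.append(
                {
                    "tissue": res.tissue,
                    "ld_subset": res.ld_subset,
                    "index_variant": idx,
                    "member_variants": ",".join(res.members.get(idx, [])),
                }
            )
        if not res.index_variants:
            rows.append(
                {
                    "tissue": res.tissue,
                    "ld_subset": res.ld_subset,
                    "index_variant": "",
                    "member_variants": "",
                }
            )
    return pd.DataFrame(rows, columns=["tissue", "ld_subset", "index_variant", "member_variants"])


def clumps_from_frame(df: pd.DataFrame) -> list[ClumpResult]:
    """Inverse of :func:`clumps_to_frame`."""
    results = []
    for (tissue, subset), sub in df.groupby(["tissue", "ld_subset"], sort=False):
        index_variants = []
        members: dict[str, list[str]] = {}
        for row in sub.itertuples(index=False):
            iv = row.index_variant
            if not isinstance(iv, str) or iv == "":  # empty-result placeholder row
                continue
            mv = row.member_variants
            index_variants.append(iv)
            members[iv] = mv.split(",") if isinstance(mv, str) and mv else []
        results.append(
            ClumpResult(
                tissue=str(tissue),
                ld_subset=str(subset),
                index_variants=index_variants,
                members=members,
            )
        )
    return results
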