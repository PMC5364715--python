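"""Per-individual, per-tissue polygenic scores of genetically determined
expression.

The score of individual *i* for tissue *t* is the weighted allele sum

    score(i, t) = sum over index variants v of  beta(v, t) * dosage(i, v)

over the tissue's clumped index variants, with the weights already oriented to
the alt-dosage scale.  A missing dosage is replaced by the variant's mean alt
dosage over the score cohort, so the cohort size is constant across tissues.
No per-allele averaging or standardization is applied (the downstream tests
are rank-based and invariant to either).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .clump import ClumpResult
from .io import GenotypeRegion, SamplePanel, WeightTable


class ScoreConsistencyError(ValueError):
    """An index variant lacks a weight row, or a dosage column is unusable."""


@dataclass
class ScoreMatrix:
    """[n_samples x n_tissues] score values with sample and tissue labels."""

    scores: np.ndarray
    sample_ids: list[str]
    tissues: list[str]
    perspective: str = "among"
    group: str | None = None  # set for the within-ancestry perspective

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.tissues)):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.tissues)} tissues"
            )
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite (missing dosages resolved first)")

    def column(self, tissue: str) -> np.ndarray:
        return self.scores[:, self.tissues.index(tissue)]

    def to_long_frame(self, panel: SamplePanel) -> pd.DataFrame:
        pops = panel.labels_for(self.sample_ids, "population")
        groups = panel.labels_for(self.sample_ids, "ancestry")
        frames = []
        for t_idx, tissue in enumerate(self.tissues):
            frames.append(
                pd.DataFrame(
                    {
                        "sample": self.sample_ids,
                        "population": pops,
                        "ancestry": groups,
                        "tissue": tissue,
                        "score": self.scores[:, t_idx],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long_frame(
        cls,
        df: pd.DataFrame,
        perspective: str = "among",
        group: str | None = None,
    ) -> "ScoreMatrix":
        sample_ids = list(dict.fromkeys(df["sample"]))
        tissues = list(dict.fromkeys(df["tissue"]))
        wide = df.pivot(index="sample", columns="tissue", values="score")
        wide = wide.loc[sample_ids, tissues]
        return cls(
            scores=wide.to_numpy(),
            sample_ids=sample_ids,
            tissues=tissues,
            perspective=perspective,
            group=group,
        )


def compute_scores(
    region: GenotypeRegion,
    weights: WeightTable,
    clumps: Iterable[ClumpResult],
    samples: Sequence[str],
    perspective: str = "among",
    group: str | None = None,
) -> ScoreMatrix:
    """Score the given cohort for every tissue covered by ``clumps``.

    ``weights`` must already be aligned to the alt-dosage scale.  Missing
    dosages are mean-imputed per variant within ``samples`` (a no-op when no
    call is missing).  A tissue whose clump result retains no index variant
    scores 0 for everyone.
    """
    clump_by_tissue = {c.tissue: c for c in clumps}
    tissues = [t for t in weights.tissues if t in clump_by_tissue]
    missing = set(clump_by_tissue) - set(tissues)
    if missing:
        raise ScoreConsistencyError(f"clump results for unknown tissues: {sorted(missing)}")
    rows = region.sample_indices(samples)
    out = np.zeros((len(samples), len(tissues)))
    for t_idx, tissue in enumerate(tissues):
        betas = weights.beta_lookup(tissue)
        for vid in clump_by_tissue[tissue].index_variants:
            if vid not in betas:
                raise ScoreConsistencyError(
                    f"index variant {vid!r} has no weight row for tissue {tissue!r}"
                )
            col = region.dosages[rows, region.variant_index(vid)]
            nan = np.isnan(col)
            if nan.any():
                if nan.all():
                    raise ScoreConsistencyError(
                        f"variant {vid!r} has no observed genotype in the score cohort"
                    )
                col = np.where(nan, np.nanmean(col), col)
            out[:, t_idx] += betas[vid] * col
    return ScoreMatrix(
        scores=out,
        sample_ids=list(samples),
        tissues=tissues,
        perspective=perspective,
        group=group,
    )


def summarize_scores(
    scores: ScoreMatrix,
    panel: SamplePanel,
    level: Literal["population", "ancestry"] = "population",
) -> pd.DataFrame:
    """Median/min/max of scores per (group, tissue); one row per pair."""
    labels = np.array(panel.labels_for(scores.sample_ids, level))
    rows = []
    for grp in dict.fromkeys(labels):
        mask = labels == grp
        if not mask.any():
            raise ValueError(f"empty group {grp!r}")
        for t_idx, tissue in enumerate(scores.tissues):
            vals = scores.scores[mask, t_idx]
            rows.append(
                {
                    level: grp,
                    "tissue": tissue,
                    "n": int(mask.sum()),
                    "median": float(np.median(vals)),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows, columns=[level, "tissue", "n", "median", "min", "max"])
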