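from __future__ import annotations

import numpy as np
import pytest

import popscore as ps
from popscore.io import GenotypeRegion, VariantRecord


def make_region(
    dosages,
    positions=None,
    chrom: str = "18",
    sample_ids=None,
    ids=None,
) -> GenotypeRegion:
    """Build a GenotypeRegion directly from a dosage matrix (tests only)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = [29_155_000 + 100 * (k + 1) for k in range(m)]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if ids is None:
        ids = [f"v{k}" for k in range(m)]
    variants = [
        VariantRecord(chrom=chrom, pos=int(p), id=i, ref="A", alt="G")
        for p, i in zip(positions, ids)
    ]
    return GenotypeRegion(variants=variants, dosages=dosages, sample_ids=sample_ids)


def make_weights(variant_ids, tissues, betas, pvalues, region=None):
    """Weight table for the given ids; betas/pvalues indexed [tissue][variant]."""
    import pandas as pd

    from popscore.io import WEIGHT_COLUMNS, WeightTable

    meta = {}
    if region is not None:
        meta = {v.id: v for v in region.variants}
    rows = []
    for k, vid in enumerate(variant_ids):
        for t_idx, tissue in enumerate(tissues):
            rec = meta.get(vid)
            rows.append(
                {
                    "variant_id": vid,
                    "chrom": rec.chrom if rec else "18",
                    "pos": rec.pos if rec else 29_155_000 + 100 * (k + 1),
                    "ref": rec.ref if rec else "A",
                    "alt": rec.alt if rec else "G",
                    "effect_allele": rec.alt if rec else "G",
                    "tissue": tissue,
                    "beta": float(betas[t_idx][k]),
                    "pvalue": float(pvalues[t_idx][k]),
                }
            )
    return WeightTable(df=pd.DataFrame(rows, columns=WEIGHT_COLUMNS))


@pytest.fixture(scope="session")
def small_sim() -> ps.SimData:
    """A small but structured synthetic dataset shared across tests."""
    cfg = ps.SimConfig(
        n_variants=40,
        n_tissues=3,
        seed=7,
        groups=[
            ("G1", [("P1", 40), ("P2", 40)]),
            ("G2", [("P3", 40), ("P4", 40)]),
        ],
    )
    return ps.simulate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
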