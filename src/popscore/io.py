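"""Readers and writers for the pipeline's three inputs and its result tables.

Inputs are a region VCF of diploid genotypes, a tab-delimited per-tissue eQTL
weight table, and a two-level sample panel (sample -> population -> ancestry
group, following the 1000 Genomes ``.panel`` layout).  All coordinates are
1-based inclusive, the VCF convention.  Missing genotype dosages are stored as
``NaN`` in a float matrix, never silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order required of a weight table file.
WEIGHT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "effect_allele",
    "tissue",
    "beta",
    "pvalue",
]

_NUCLEOTIDES = frozenset("ACGT")


class ValidationError(ValueError):
    """An input file violates a documented invariant."""


class VCFParseError(ValueError):
    """The VCF could not be parsed."""


class EmptyRegionError(ValueError):
    """No biallelic SNP fell inside the requested interval."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: multi-allelic and indel records are excluded at load."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"variant {self.id}: ref equals alt ({self.ref})")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError(f"variant {self.id}: not a SNP ({self.ref}>{self.alt})")


@dataclass
class GenotypeRegion:
    """Biallelic variants plus an [n_samples x n_variants] alt-dosage matrix.

    Dosages are floats in {0, 1, 2} with ``NaN`` marking a missing genotype
    (a half-missing diploid call is treated as fully missing).
    """

    variants: list[VariantRecord]
    dosages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be in {0, 1, 2} or missing")
        positions = [v.pos for v in self.variants]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValidationError("variants must be strictly increasing by position")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Row indices of the given samples; unknown ids raise ``KeyError``."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def variant_index(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == variant_id:
                return i
        raise KeyError(f"unknown variant id {variant_id!r}")


@dataclass
class WeightTable:
    """Per-variant, per-tissue eQTL effect sizes and association p-values.

    Backed by a DataFrame with :data:`WEIGHT_COLUMNS`; ``tissues`` preserves
    first-appearance file order, de-duplicated.
    """

    df: pd.DataFrame
    tissues: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"weight table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        pv = self.df["pvalue"].to_numpy(dtype=float)
        if np.any(pv <= 0) or np.any(pv > 1) or np.any(~np.isfinite(pv)):
            raise ValidationError("pvalue must lie in (0, 1]")
        dup = self.df.duplicated(subset=["variant_id", "tissue"])
        if dup.any():
            pair = self.df.loc[dup.idxmax(), ["variant_id", "tissue"]].tolist()
            raise ValidationError(f"duplicate (variant, tissue) row: {pair}")
        if not self.tissues:
            self.tissues = list(dict.fromkeys(self.df["tissue"]))

    def __len__(self) -> int:
        return len(self.df)

    def for_tissue(self, tissue: str) -> pd.DataFrame:
        if tissue not in self.tissues:
            raise KeyError(f"tissue {tissue!r} not in weight table")
        return self.df[self.df["tissue"] == tissue]

    def beta_lookup(self, tissue: str) -> dict[str, float]:
        sub = self.for_tissue(tissue)
        return dict(zip(sub["variant_id"], sub["beta"].astype(float)))


@dataclass
class SamplePanel:
    """sample -> population -> ancestry-group labels (1000 Genomes layout)."""

    df: pd.DataFrame  # columns: sample, pop, group

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        for col in ("sample", "pop", "group"):
            if col not in self.df.columns:
                raise ValidationError(f"panel missing column {col!r}")
        dup = self.df[self.df.duplicated(subset="sample", keep=False)]
        for sample, sub in dup.groupby("sample"):
            if sub[["pop", "group"]].drop_duplicates().shape[0] > 1:
                raise ValidationError(f"sample {sample!r} listed with conflicting labels")
        self.df = self.df.drop_duplicates(subset="sample").reset_index(drop=True)
        pop_groups = self.df.groupby("pop")["group"].nunique()
        bad = pop_groups[pop_groups > 1]
        if len(bad):
            raise ValidationError(f"population(s) mapped to multiple groups: {list(bad.index)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return list(self.df["sample"])

    @property
    def groups(self) -> list[str]:
        """Ancestry groups in panel (first appearance) order."""
        return list(dict.fromkeys(self.df["group"]))

    def populations(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(dict.fromkeys(self.df["pop"]))
        sub = self.df[self.df["group"] == group]
        if sub.empty:
            raise KeyError(f"unknown ancestry group {group!r}")
        return list(dict.fromkeys(sub["pop"]))

    def samples_in_group(self, group: str) -> list[str]:
        sub = self.df[self.df["group"] == group]
        if sub.empty:
            raise KeyError(f"unknown ancestry group {group!r}")
        return list(sub["sample"])

    def samples_in_population(self, pop: str) -> list[str]:
        return list(self.df.loc[self.df["pop"] == pop, "sample"])

    def pop_of(self, sample: str) -> str:
        row = self.df.loc[self.df["sample"] == sample]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in panel")
        return row["pop"].iloc[0]

    def labels_for(self, sample_ids: Sequence[str], level: str) -> list[str]:
        """Population or ancestry-group label per sample, in the given order."""
        col = {"population": "pop", "ancestry": "group"}[level]
        lookup = dict(zip(self.df["sample"], self.df[col]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"samples missing from panel: {missing[:5]}")
        return [lookup[s] for s in sample_ids]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_region_vcf(path: str | Path, chrom: str, start: int, end: int) -> GenotypeRegion:
    """Read biallelic SNPs in ``chrom:start-end`` (1-based inclusive) from a VCF.

    Phased and unphased GT fields are both converted to alt-allele dosage;
    any genotype with a missing allele becomes a fully missing (NaN) dosage.
    Multi-allelic and indel records are excluded.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VCFParseError(f"{path}: cannot open VCF: {exc}") from exc

    samples = list(vcf.samples)
    want = _norm_chrom(chrom)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    record_no = 0
    try:
        for v in vcf:
            record_no += 1
            if _norm_chrom(v.CHROM) != want or not (start <= v.POS <= end):
                continue
            if len(v.ALT) != 1:
                continue
            ref, alt = v.REF, v.ALT[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
                continue
            vid = v.ID if v.ID not in (None, ".", "") else f"{v.CHROM}:{v.POS}:{ref}:{alt}"
            gts = v.genotypes  # [[a0, a1, phased], ...]
            col = np.empty(len(samples), dtype=float)
            for i, gt in enumerate(gts):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    col[i] = np.nan
                else:
                    col[i] = float(sum(alleles))
            variants.append(VariantRecord(chrom=v.CHROM, pos=v.POS, id=vid, ref=ref, alt=alt))
            columns.append(col)
    except VCFParseError:
        raise
    except Exception as exc:
        raise VCFParseError(f"{path}: malformed VCF near record {record_no}: {exc}") from exc

    if not variants:
        raise EmptyRegionError(f"{path}: no biallelic SNP in {chrom}:{start}-{end}")

    order = sorted(range(len(variants)), key=lambda i: (variants[i].pos, variants[i].id))
    variants = [variants[i] for i in order]
    dosages = np.column_stack([columns[i] for i in order])
    return GenotypeRegion(variants=variants, dosages=dosages, sample_ids=samples)


def read_weight_table(path: str | Path) -> WeightTable:
    """Read a tab-delimited weight table with the nine required columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return WeightTable(df=df)


def read_panel(path: str | Path) -> SamplePanel:
    """Read a sample panel (whitespace/tab delimited; header auto-detected)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = "sample" in first.lower().split()
    df = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None)
    if has_header:
        df.columns = [c.lower() for c in df.columns]
        rename = {"super_pop": "group", "superpop": "group"}
        df = df.rename(columns=rename)
        df = df[["sample", "pop", "group"]]
    else:
        if df.shape[1] < 3:
            raise ValidationError(f"{path}: panel needs >= 3 columns (sample pop group)")
        df = df.iloc[:, :3]
        df.columns = ["sample", "pop", "group"]
    return SamplePanel(df=df.astype(str))


def align_weights_to_genotypes(region: GenotypeRegion, weights: WeightTable) -> WeightTable:
    """Orient every weight row onto the region's alt-dosage scale.

    A row whose effect allele is the VCF ref allele has its beta negated and
    the effect allele rewritten to alt.  Rows whose variant id or allele pair
    does not match any region variant are dropped with a logged warning
    (alleles are matched literally; no strand flipping is attempted).
    """
    by_id = {v.id: v for v in region.variants}
    rows = []
    n_dropped = 0
    for row in weights.df.itertuples(index=False):
        rec = by_id.get(row.variant_id)
        if rec is None or {row.ref, row.alt} != {rec.ref, rec.alt}:
            n_dropped += 1
            continue
        d = row._asdict()
        d["ref"], d["alt"] = rec.ref, rec.alt
        if row.effect_allele == rec.alt:
            pass
        elif row.effect_allele == rec.ref:
            d["beta"] = -float(row.beta)
            d["effect_allele"] = rec.alt
        else:
            n_dropped += 1
            continue
        rows.append(d)
    if n_dropped:
        logger.warning("align_weights_to_genotypes: dropped %d unmatched weight rows", n_dropped)
    if not rows:
        raise ValidationError("no weight row matched the genotype region")
    df = pd.DataFrame(rows, columns=weights.df.columns)
    tissues = [t for t in weights.tissues if t in set(df["tissue"])]
    return WeightTable(df=df, tissues=tissues)


# ---------------------------------------------------------------------------
# writers (all outputs TSV; VCF for the genotype fixture)
# ---------------------------------------------------------------------------


def write_region_vcf(region: GenotypeRegion, path: str | Path) -> Path:
    """Write a minimal VCF 4.2 with unphased GT calls."""
    path = Path(path)
    dos = region.dosages
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in region.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(region.sample_ids)
            + "\n"
        )
        for j, v in enumerate(region.variants):
            calls = [
                "./." if np.isnan(dos[i, j]) else gt_strings[dos[i, j]]
                for i in range(region.n_samples)
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )
    return path


def write_weight_table(weights: WeightTable, path: str | Path) -> Path:
    path = Path(path)
    weights.df.to_csv(path, sep="\t", index=False)
    return path


def write_panel(panel: SamplePanel, path: str | Path) -> Path:
    path = Path(path)
    panel.df.to_csv(path, sep="\t", index=False)
    return path


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table; shared by every pipeline stage for determinism."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
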