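"""Synthetic genotype, eQTL-weight and panel generation.

The generator emulates the statistical shape of the study inputs: a ~40-kb
gene region of ~130 biallelic SNPs with block-wise LD, a two-level population
structure (ancestry groups containing populations) with Balding–Nichols
allele-frequency differentiation, and per-tissue weight tables mixing "effect"
variants (small p, full-scale beta) with "null" variants (uniform p, shrunken
beta).  Weight-table p-values are simulated labels consumed as given — the
pipeline never re-estimates eQTLs.

Population structure is hierarchical: each variant has an ancestral frequency
p0 ~ Uniform(0.05, 0.95); each ancestry group draws a group-level frequency
from Beta(p0(1-F)/F, (1-p0)(1-F)/F) with the group differentiation F; each
population inside the group draws around the group frequency with F/5.  An
optional differential injection shifts one population's frequency at the
largest-|beta| variants of one tissue; the shift is applied in the direction
of each variant's effect (freq += delta * sign(beta)) so the injected
population's score moves coherently, and frequencies are clipped to
[0.01, 0.99].

Haplotypes use first-order Markov copying: each variant's latent frequency
quantile is the previous variant's with probability ``ld_rho`` and a fresh
uniform otherwise, producing r² that decays with distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .io import GenotypeRegion, SamplePanel, VariantRecord, WeightTable

#: The 14 GTEx tissue labels used throughout as the default tissue set.
DEFAULT_TISSUES = [
    "Colon - Transverse",
    "Colon - Sigmoid",
    "Esophagus - Muscularis",
    "Esophagus - Mucosa",
    "Heart - Atrial Appendage",
    "Heart - Left Ventricle",
    "Liver",
    "Muscle - Skeletal",
    "Nerve - Tibial",
    "Stomach",
    "Small Intestine - Terminal Ileum",
    "Adipose - Subcutaneous",
    "Cells - Transformed fibroblasts",
    "Skin - Sun Exposed (Lower leg)",
]

#: 1000 Genomes Phase 3 panel structure (population, sample count) per
#: superpopulation group; totals N = 2,504 across 26 populations.
DEFAULT_GROUPS: list[tuple[str, list[tuple[str, int]]]] = [
    ("AFR", [("ACB", 96), ("ASW", 61), ("ESN", 99), ("GWD", 113), ("LWK", 99), ("MSL", 85), ("YRI", 108)]),
    ("AMR", [("CLM", 94), ("MXL", 64), ("PEL", 85), ("PUR", 104)]),
    ("EAS", [("CDX", 93), ("CHB", 103), ("CHS", 105), ("JPT", 104), ("KHV", 99)]),
    ("EUR", [("CEU", 99), ("FIN", 99), ("GBR", 91), ("IBS", 107), ("TSI", 107)]),
    ("SAS", [("BEB", 86), ("GIH", 103), ("ITU", 102), ("PJL", 96), ("STU", 102)]),
]


@dataclass(frozen=True)
class DifferentialSpec:
    """Inject a frequency shift for one population at one tissue's top-|beta|
    variants (shift direction follows each variant's effect sign)."""

    population: str
    tissue: str
    delta_freq: float
    n_top: int = 5


@dataclass
class SimConfig:
    n_variants: int = 130
    chrom: str = "18"
    region_start: int = 29_155_000
    region_end: int = 29_195_000
    groups: list[tuple[str, list[tuple[str, int]]]] = field(
        default_factory=lambda: [(g, list(pops)) for g, pops in DEFAULT_GROUPS]
    )
    fst: float = 0.1
    ld_rho: float = 0.8
    n_tissues: int = 14
    tissues: list[str] | None = None
    prop_effect_variants: float = 0.3
    beta_sd: float = 0.5
    differential_spec: list[DifferentialSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fst < 1):
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        if not (0 <= self.ld_rho < 1):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not (0 <= self.prop_effect_variants <= 1):
            raise ValueError("prop_effect_variants must be in [0, 1]")
        for _, pops in self.groups:
            for pop, n in pops:
                if n < 1:
                    raise ValueError(f"population {pop!r} needs >= 1 sample")
        if self.tissues is None:
            if self.n_tissues <= len(DEFAULT_TISSUES):
                self.tissues = DEFAULT_TISSUES[: self.n_tissues]
            else:
                self.tissues = DEFAULT_TISSUES + [
                    f"Tissue {k}" for k in range(len(DEFAULT_TISSUES), self.n_tissues)
                ]
        self.n_tissues = len(self.tissues)

    @property
    def populations(self) -> list[tuple[str, str, int]]:
        """(group, population, n) triples in config order."""
        return [(g, pop, n) for g, pops in self.groups for pop, n in pops]

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = [(g, [(p, int(n)) for p, n in pops]) for g, pops in d["groups"]]
        if "differential_spec" in d:
            d["differential_spec"] = [
                DifferentialSpec(**ds) if isinstance(ds, dict) else DifferentialSpec(*ds)
                for ds in d["differential_spec"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Generator ground truth: frequencies, effect structure, injections."""

    p0: np.ndarray  # ancestral frequency per variant
    group_freq: dict[str, np.ndarray]
    pop_freq: dict[str, np.ndarray]
    betas: dict[str, np.ndarray]  # tissue -> per-variant beta
    pvalues: dict[str, np.ndarray]
    effect_mask: np.ndarray  # bool, variants with full-scale betas
    injected: list[tuple[str, str, int, float]]  # (pop, tissue, variant index, applied delta)

    def __post_init__(self) -> None:
        for freqs in self.pop_freq.values():
            if np.any(freqs <= 0) or np.any(freqs >= 1):
                raise ValueError("population frequencies must lie in (0, 1)")


def _balding_nichols(rng: np.random.Generator, base: np.ndarray, f: float) -> np.ndarray:
    a = base * (1.0 - f) / f
    b = (1.0 - base) * (1.0 - f) / f
    draw = rng.beta(a, b)
    return np.clip(draw, 1e-4, 1.0 - 1e-4)


def simulate_weights(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    """Draw the effect structure: per-tissue betas and p-value labels.

    A global effect-variant set of size round(prop_effect_variants x
    n_variants) gets beta ~ N(0, beta_sd^2) and p ~ U(1e-8, 0.01) in every
    tissue; the remaining (null) variants get beta ~ N(0, (beta_sd/10)^2) and
    p ~ U(0, 1).  Frequencies are filled in by :func:`simulate_frequencies`.
    """
    m = config.n_variants
    n_effect = int(round(config.prop_effect_variants * m))
    effect_idx = rng.choice(m, size=n_effect, replace=False)
    effect_mask = np.zeros(m, dtype=bool)
    effect_mask[effect_idx] = True
    betas, pvals = {}, {}
    for tissue in config.tissues:
        beta = rng.normal(0.0, config.beta_sd / 10.0, size=m)
        beta[effect_mask] = rng.normal(0.0, config.beta_sd, size=n_effect)
        p = rng.uniform(0.0, 1.0, size=m)
        p[p == 0.0] = np.nextafter(0.0, 1.0)
        p[effect_mask] = rng.uniform(1e-8, 0.01, size=n_effect)
        betas[tissue] = beta
        pvals[tissue] = p
    return SimTruth(
        p0=np.empty(0),
        group_freq={},
        pop_freq={pop: np.full(m, 0.5) for _, pop, _ in config.populations},
        betas=betas,
        pvalues=pvals,
        effect_mask=effect_mask,
        injected=[],
    )


def simulate_frequencies(
    config: SimConfig, rng: np.random.Generator, truth: SimTruth | None = None
) -> SimTruth:
    """Two-level Balding–Nichols frequencies, with differential injection last.

    ``truth`` (from :func:`simulate_weights`) supplies the betas needed to
    locate the top-|beta| variants of an injected tissue; without it the
    differential_spec must be empty.
    """
    m = config.n_variants
    p0 = rng.uniform(0.05, 0.95, size=m)
    group_freq: dict[str, np.ndarray] = {}
    pop_freq: dict[str, np.ndarray] = {}
    for group, pops in config.groups:
        gf = _balding_nichols(rng, p0, config.fst)
        group_freq[group] = gf
        for pop, _n in pops:
            pop_freq[pop] = _balding_nichols(rng, gf, config.fst / 5.0)

    injected: list[tuple[str, str, int, float]] = []
    if config.differential_spec:
        if truth is None:
            raise ValueError("differential_spec requires the effect truth (betas)")
        for spec in config.differential_spec:
            beta = truth.betas[spec.tissue]
            order = np.argsort(-np.abs(beta))
            targets = order[: spec.n_top]
            for v in targets:
                delta = spec.delta_freq * np.sign(beta[v])
                before = pop_freq[spec.population][v]
                after = float(np.clip(before + delta, 0.01, 0.99))
                pop_freq[spec.population][v] = after
                injected.append((spec.population, spec.tissue, int(v), after - before))

    if truth is None:
        truth = SimTruth(
            p0=p0,
            group_freq=group_freq,
            pop_freq=pop_freq,
            betas={},
            pvalues={},
            effect_mask=np.zeros(m, dtype=bool),
            injected=injected,
        )
        return truth
    return replace(
        truth, p0=p0, group_freq=group_freq, pop_freq=pop_freq, injected=injected
    )


def _variant_meta(config: SimConfig, rng: np.random.Generator) -> list[VariantRecord]:
    m = config.n_variants
    positions = np.linspace(config.region_start, config.region_end, m + 2)[1:-1]
    positions = np.round(positions).astype(int)
    if len(np.unique(positions)) != m:
        raise ValueError("region too narrow for the requested variant count")
    nts = np.array(list("ACGT"))
    records = []
    for k in range(m):
        ref, alt = rng.choice(nts, size=2, replace=False)
        records.append(
            VariantRecord(
                chrom=config.chrom,
                pos=int(positions[k]),
                id=f"snp{k:04d}",
                ref=str(ref),
                alt=str(alt),
            )
        )
    return records


def simulate_genotypes(
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
    variants: list[VariantRecord] | None = None,
) -> tuple[GenotypeRegion, SamplePanel]:
    """Markov-copying haplotypes per population, summed to dosages.

    Each haplotype carries a latent uniform per variant; with probability
    ``ld_rho`` the previous variant's uniform is copied, otherwise a fresh one
    is drawn; the allele is 1 when the uniform falls below the population's
    frequency.  Two haplotypes per individual are summed to a dosage.
    """
    if variants is None:
        variants = _variant_meta(config, rng)
    m = config.n_variants
    dosage_blocks = []
    panel_rows = []
    for group, pop, n in config.populations:
        freqs = truth.pop_freq[pop]
        n_hap = 2 * n
        u = np.empty((n_hap, m))
        u[:, 0] = rng.random(n_hap)
        for j in range(1, m):
            copy = rng.random(n_hap) < config.ld_rho
            fresh = rng.random(n_hap)
            u[:, j] = np.where(copy, u[:, j - 1], fresh)
        hap = (u < freqs[None, :]).astype(float)
        dosage_blocks.append(hap[0::2, :] + hap[1::2, :])
        panel_rows += [
            {"sample": f"{pop}_{i:04d}", "pop": pop, "group": group} for i in range(n)
        ]
    panel = SamplePanel(df=pd.DataFrame(panel_rows))
    region = GenotypeRegion(
        variants=variants,
        dosages=np.vstack(dosage_blocks),
        sample_ids=panel.samples,
    )
    return region, panel


def weights_to_table(
    truth: SimTruth, config: SimConfig, variants: list[VariantRecord]
) -> WeightTable:
    """Materialize the effect truth as a weight table (effect allele = alt)."""
    rows = []
    for k, v in enumerate(variants):
        for tissue in config.tissues:
            rows.append(
                {
                    "variant_id": v.id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "effect_allele": v.alt,
                    "tissue": tissue,
                    "beta": float(truth.betas[tissue][k]),
                    "pvalue": float(truth.pvalues[tissue][k]),
                }
            )
    return WeightTable(df=pd.DataFrame(rows, columns=pio.WEIGHT_COLUMNS))


@dataclass
class SimData:
    region: GenotypeRegion
    panel: SamplePanel
    weights: WeightTable
    truth: SimTruth
    config: SimConfig


def simulate_dataset(config: SimConfig) -> SimData:
    """Full draw: effect structure, frequencies (with injections), genotypes."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_weights(config, rng)
    truth = simulate_frequencies(config, rng, truth)
    variants = _variant_meta(config, rng)
    region, panel = simulate_genotypes(truth, config, rng, variants=variants)
    weights = weights_to_table(truth, config, variants)
    return SimData(region=region, panel=panel, weights=weights, truth=truth, config=config)


def write_fixture(
    region: GenotypeRegion,
    panel: SamplePanel,
    weights: WeightTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write VCF + weight TSV + panel so data_io can round-trip them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return {
        "vcf": pio.write_region_vcf(region, out_dir / "region.vcf"),
        "weights": pio.write_weight_table(weights, out_dir / "weights.tsv"),
        "panel": pio.write_panel(panel, out_dir / "panel.tsv"),
    }
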