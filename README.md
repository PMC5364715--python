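# popscore

Population comparison of **genetically determined, tissue-specific gene
expression**, estimated as eQTL-weighted polygenic scores.

Regulatory (non-coding) variants shift how strongly a gene is expressed in
each tissue, and their allele frequencies differ between human populations.
For a gene such as *TTR* (transthyretin, whose misfolded variants cause
hereditary amyloidosis with strikingly population-specific clinical
presentations), this raises a concrete question: **does the genetically
determined expression of the gene differ among populations, tissue by
tissue?** `popscore` implements the full analysis for one genomic region:

1. **Inputs** — a region VCF of diploid genotypes (e.g. 1000 Genomes Phase 3,
   chr18:29,155,000–29,195,000), a per-tissue eQTL weight table (variant,
   effect allele, beta, p-value per tissue, e.g. GTEx), and a two-level
   sample panel (sample → population → ancestry group).
2. **LD clumping** — per tissue, variants with at least a trend association
   (p ≤ 0.1) are greedily reduced to approximately independent index variants
   (r² ≥ 0.5 within ±10 kb absorbs a variant into the current best-p index),
   with the LD reference taken from all samples (among-ancestry analysis) or
   from one ancestry group (within-ancestry analysis).
3. **Scoring** — per individual *i* and tissue *t*,

   `score(i, t) = Σ_v  β(v, t) · dosage(i, v)`

   summed over the tissue's index variants, with betas oriented to the
   alternate-allele dosage scale and missing dosages mean-imputed within the
   score cohort.
4. **Comparisons** — Kruskal–Wallis across ancestry groups (among) or across
   populations within each group (within), Dunn's rank-based post-hoc z for
   every pair, Bonferroni correction over the tissues tested.
5. **Permutation null** — for within-ancestry findings, population labels are
   shuffled (scores fixed) to build an empirical null of the Dunn z;
   the two-sided empirical p uses the add-one rule
   `p = (1 + #{|z_perm| ≥ |z_obs|}) / (1 + n_perm)`.

A first-class synthetic-data module (`popscore.simulate`) emulates the study
inputs — Balding–Nichols two-level population structure, Markov-copying LD,
and per-tissue weight vectors mixing effect and null variants — so the whole
pipeline is exercisable and testable offline.

## Worked example

```python
import popscore as ps

cfg = ps.SimConfig(
    seed=42,
    n_variants=60,
    n_tissues=3,
    groups=[("EUR", [("FIN", 80), ("TSI", 80), ("IBS", 80)]),
            ("EAS", [("CHB", 80), ("JPT", 80)])],
    # shift one population's allele frequencies at the 5 strongest-effect
    # variants of one tissue
    differential_spec=[ps.DifferentialSpec("FIN", "Colon - Transverse", 0.25, n_top=5)],
)
sim = ps.simulate_dataset(cfg)

clumps = ps.clump_all(sim.region, sim.weights, sim.panel, perspective="within")
eur = [c for c in clumps if c.ld_subset == "EUR"]
scores = ps.compute_scores(sim.region, sim.weights, eur,
                           sim.panel.samples_in_group("EUR"), "within", "EUR")
report = ps.run_comparisons([scores], sim.panel, "within")
print(report.kw[["tissue", "H", "p_nominal", "p_bonferroni"]].to_string(index=False))
```

prints

```
                tissue         H    p_nominal  p_bonferroni
    Colon - Transverse 73.231312 1.253206e-16  3.759619e-16
       Colon - Sigmoid 18.849528 8.070064e-05  2.421019e-04
Esophagus - Muscularis 10.956945 4.175703e-03  1.252711e-02
```

The injected tissue dominates: its Kruskal–Wallis H (73.2 on 2 df across the
three European populations) survives Bonferroni correction over the three
tissues by sixteen orders of magnitude.  Following up with Dunn's post-hoc
test and the permutation null:

```python
top = report.dunn.sort_values("p_nominal").iloc[0]
perm = ps.permute_null(scores, sim.panel, top["tissue"], "EUR",
                       [(top["group_a"], top["group_b"])], n_perm=99_999, seed=7)[0]
```

reports `FIN vs IBS (Colon - Transverse), z = 7.62, p = 2.49e-14` and
`empirical p = 1e-05 (null 99.9% quantile of z: 3.08)`: the observed z sits
far beyond the permutation null's extreme quantile, and its empirical p is at
the floor the add-one estimator allows for 99,999 permutations — the injected
population is recovered as the driver of the difference.

The same analysis is available from the shell:

```bash
popscore simulate --seed 42 --out fixtures/
popscore run --simulate --seed 42 --n-perm 100000 --out results/
popscore run --vcf region.vcf --weights weights.tsv --panel samples.panel --out results/
```

`run` executes both perspectives end to end and writes TSV tables (clumps,
scores, score summaries, Kruskal–Wallis and Dunn results, permutation
results) plus a JSON manifest with versions, seed, parameters and input
checksums; identical config + seed reproduces every output byte-for-byte.

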