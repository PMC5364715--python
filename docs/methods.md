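# Methods

## The quantity being compared

For each tissue *t* the pipeline estimates, per individual *i*, the
genetically determined component of a gene's expression as a weighted allele
sum

```
score(i, t) = Σ_v β(v, t) · d(i, v)
```

where the sum runs over the tissue's LD-clumped index variants, β(v, t) is
the eQTL effect size of variant *v* on expression in tissue *t* (expression
units per alternate allele), and d(i, v) ∈ {0, 1, 2} is the alternate-allele
dosage.  The score is a genotype-only surrogate for expression: no expression
measurements enter the analysis, and the weight table's p-values are consumed
as given, never re-estimated.  Scores are deliberately left unstandardized
(no per-allele averaging, no z-scaling) because every downstream test is
rank-based and invariant to strictly increasing transforms within a fixed
variant set.

Two perspectives are always computed separately and never mixed: the
among-ancestry analysis (LD reference = all samples; ancestry groups
compared) and the within-ancestry analysis (per group: LD reference = the
group's samples; the group's populations compared).  The index sets, and
therefore the scores, legitimately differ between perspectives because LD
structure differs between a pooled panel and a single ancestry group.

## Effect-allele orientation

The weight table declares an effect allele per variant.  Before any analysis
every weight row is normalized onto the alternate-dosage scale of the
genotype file: if the declared effect allele equals the VCF reference allele,
β is negated and the effect allele rewritten to the alternate allele.
Alleles are matched literally — no strand flipping or palindromic-SNP
resolution is attempted — because both inputs are assumed to share one
harmonized reference build for a single small region.  Rows whose variant id
or allele pair matches nothing in the region are dropped with a logged
warning rather than raising: a partially matching weight table is a normal
condition when variant universes differ.

## LD clumping

Clumping follows the classic greedy convention of Plink's `--clump`
(re-implemented here, not called): among the tissue's variants with
p ≤ `p_threshold` (default 0.1 — "at least a trend effect"), the remaining
candidate with the smallest p becomes an index variant and absorbs every
unassigned candidate within ±`window_kb` (default 10 kb) whose squared dosage
correlation with it is ≥ `r2_threshold` (default 0.5), repeating until all
candidates are assigned.  Design points:

- one p cutoff applies to index and absorbed variants alike (no separate
  p1/p2);
- r² is the squared Pearson correlation of unphased alt-allele dosages over
  the LD-reference samples with complete genotypes at both variants
  (dosage-level inputs need no phase and no haplotype EM);
- an undefined r² (monomorphic variant in the subset, or fewer than two
  complete pairs) is treated as 0 — no evidence of dependence, no clumping;
- ties in p break deterministically by (position, variant id), and member
  lists are serialized in genomic order, so results are reproducible
  bit-for-bit;
- the window is measured from the index variant's position.

## Rank tests and multiplicity

Kruskal–Wallis H is computed on pooled mid-ranks with the standard tie
correction (divisor `1 − Σ(t³−t)/(N³−N)`) and referred to chi-square with
k−1 degrees of freedom at all sample sizes; an exact small-sample null is not
implemented because every cohort this pipeline targets has n ≥ 60 per group.
If all pooled values are tied the statistic is degenerate and (H = 0, p = 1)
is returned.

Dunn's post-hoc z for a pair (A, B) is

```
z = (R̄_A − R̄_B) / sqrt( [N(N+1)/12 − Σ(t³−t)/(12(N−1))] · (1/n_A + 1/n_B) )
```

with a two-sided normal p.  The sign convention is first-minus-second with
groups in panel order, so z(A, B) = −z(B, A).

Multiplicity: Kruskal–Wallis p-values are Bonferroni-corrected across the
tissues tested (14 by default) in both perspectives.  Dunn pairwise p-values
are additionally Bonferroni-adjusted across the pairs within a tissue; both
the nominal and adjusted values are reported so either reading of the
post-hoc family is available.

## Permutation null

For within-ancestry findings the asymptotic Dunn p is complemented by an
empirical null: the ancestry group's population labels are shuffled uniformly
(all of the group's labels jointly, once per permutation; every requested
pair evaluated on each shuffle) while the scores stay fixed — scores are not
re-derived per permutation, matching the design in which only the
label-assignment is exchangeable under the null.  Samples never cross
ancestry groups.  Because the pooled scores are fixed, the mid-ranks and the
tie-corrected variance term are computed once and a permutation reduces to
re-partitioning a fixed rank vector, which keeps the default 100,000
permutations to seconds per (group, tissue).

The two-sided empirical p uses the add-one (Phipson–Smyth style) estimator
`(1 + #{|z_perm| ≥ |z_obs|}) / (1 + n_perm)`, which is never exactly zero and
is uniform on a discrete grid under exchangeability.  In the orchestrated
pipeline, permutation is applied by default to the (group, tissue)
combinations whose Kruskal–Wallis p survived Bonferroni correction — the
findings worth quantifying further — with a `permute_all` override.

## Synthetic data model

The generator produces the three inputs with the statistical structure the
analysis assumes, and its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_variants` | 130 | biallelic SNPs, evenly spaced over chr18:29,155,000–29,195,000 (~40 kb) |
| `groups` | 1000 Genomes Phase 3 panel | 26 populations in 5 ancestry groups, published sample sizes, N = 2,504 |
| `fst` | 0.1 | among-group Balding–Nichols differentiation (continental-scale human F_ST) |
| within-group F | `fst`/5 = 0.02 | population-level differentiation inside a group (sub-continental scale) |
| `ld_rho` | 0.8 | adjacent-variant copy probability; gives block-like, distance-decaying r² |
| `n_tissues` | 14 | the study's GTEx tissue labels, shipped as the default list |
| `prop_effect_variants` | 0.3 | fraction of variants with full-scale effects in every tissue |
| `beta_sd` | 0.5 | effect-size scale (eQTL-like, expression units per allele) |

Frequencies: ancestral p₀ ~ Uniform(0.05, 0.95) per variant; group frequency
~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F); population frequency drawn the same way
around the group frequency with F/5.  Haplotypes: each variant's latent
uniform is copied from the previous variant with probability `ld_rho`, else
redrawn; the allele is 1 when the uniform falls below the population
frequency; two haplotypes sum to a dosage.  Weights: effect variants get
β ~ N(0, beta_sd²) and p ~ U(10⁻⁸, 0.01); null variants get β ~ N(0,
(beta_sd/10)²) and p ~ U(0, 1); the effect allele is always alt.

**Differential injection.**  `DifferentialSpec(population, tissue,
delta_freq, n_top)` shifts the population's frequency at the tissue's
`n_top` largest-|β| variants.  The shift is applied in the direction of each
variant's effect sign (`freq += delta_freq · sign(β)`, clipped to
[0.01, 0.99]).  This signed convention is the package's own choice: with
mixed-sign effects an unsigned shift would partially cancel in the score,
whereas the signed shift moves the injected population's score coherently,
which is what a "this population's genetically determined expression
differs" scenario means.

**Exchangeable null.**  Because populations inside a group genuinely differ
(within-group F > 0), calibration checks use `fst = 1e-4`, under which
populations are statistically identical and labels are exchangeable.  This
is the configuration behind the type-I calibration tests.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: admixture and migration (frequencies are
exchangeable draws around a group mean, not cline-structured), realistic
recombination-map LD (the Markov copier gives geometric r² decay only),
correlation between effect size and allele frequency, genotype error and
batch structure, and real GTEx effect-size distributions.  The published
p-values of any given study depend on the actual eQTL tables and genotypes
and are not reproducible from synthetic data; the tests instead establish
that each algorithmic step is exact and that the pipeline detects the
differentiation it is supposed to detect, at calibrated error rates.

## Numerical and degenerate-input choices

- Missing dosage is a distinct NaN marker, never silently 0; a half-missing
  diploid call is fully missing.  At scoring time missing dosages are
  mean-imputed per variant within the score cohort (imputation is a no-op on
  complete data; a variant with no observed call in the cohort is an error).
- p-values are clamped into (0, 1]; chi-square and normal tail probabilities
  that underflow report the smallest positive double rather than 0.
- An empty candidate set clumps to an empty index list (not an error); a
  within-perspective group with fewer than two populations, or an
  among-perspective panel with fewer than two groups, is skipped with a
  warning.
- All randomness flows through `numpy.random.default_rng` seeded from the
  run seed; per-(group, tissue) permutation seeds are spawned through
  `SeedSequence`, and the run manifest contains no timestamp, so identical
  config + seed reproduces every output file byte-for-byte.

## Problem sizes used by the test and acceptance suites

Unit tests run on toy instances (≤ 60 variants, ≤ 500 samples).  The
property-based acceptance suite uses: 1,000 random clumping instances of
≤ 30 variants × ≤ 50 samples against a brute-force oracle; 500 random
tied/untied instances for the rank statistics at 10⁻¹⁰ agreement; 1,000
null-model replicates (4 × 25 samples, 30 variants, 2 tissues) for type-I
calibration plus 300 replicates of 999-permutation empirical p for
uniformity; 200 recovery replicates at the study's per-population scale
(4 × 100 samples, 130 variants, 14 tissues); and a 5-population × 60
concordance suite at 9,999 permutations.  The acceptance script runs the
full default study conditions (N = 2,504, 130 variants, 14 tissues) with
100,000 permutations for the injected finding.

## Known limitations

- The chi-square approximation for Kruskal–Wallis is poor below ~5
  observations per group; the pipeline targets population-scale cohorts.
- Clumping is single-region and distance-based; no haplotype-aware LD, no
  sliding-window pruning, no cross-chromosome logic.
- Scores ignore interactions with coding mutations of the gene itself; the
  analysis describes the general-population regulatory background, not
  expression in mutation carriers.
- Tabix-indexed random access is not used; the region VCF is streamed and
  filtered, which is appropriate for single-gene windows but not
  chromosome-scale files.
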