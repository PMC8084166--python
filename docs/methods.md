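# Methods

Statistical models, parameter choices, and numerical details for the
`paracline` package. Notation: `n` samples, `m` SNPs, genotypes coded
0/1/2 copies of the alternate allele, `-1` missing.

## 1. Synthetic data generator (`synthetic_data`)

### Population structure: Balding–Nichols model

The design emulates a parallel latitudinal study: `n_transects = 2`
transect clades ("west", "east"), `pops_per_transect = 5` populations per
clade spanning a monotone mean-annual-temperature gradient
(`env_values = (20, 16, 11, 7, 3)` °C, south to north), and
`samples_per_pop = 10` diploid individuals per population.

Per site, each clade draws an ancestral frequency
`p̄ ~ Uniform(0.05, 0.95)` independently of the other clade; each
population of the clade then draws

```
p_pop ~ Beta( p̄ (1−F)/F , (1−p̄)(1−F)/F ),   F = fst_target (default 0.1)
```

This parameterization has two properties that make it a test oracle:

* `E[p_pop] = p̄` and `Var[p_pop] = F p̄(1−p̄)`, so the **Hudson
  ratio-of-averages F<sub>ST</sub> between two populations of one clade
  equals `F` in expectation** — the `fst_target` parameter is directly
  recoverable by the `popgen` estimator.
* Independent ancestral draws across clades create deep between-transect
  divergence, so sample trees split cleanly by transect.

### Clines

Selection is imposed at the gene level. A fraction `clinal_fraction`
(default 0.05) of genes is clinal; of those, `shared_clinal_fraction`
(default 0.5) are clinal in *both* transects (and share a single ancestral
`p̄` so the signal is homologous), the rest in one transect only. Every SNP
of a clinal gene has its population frequencies shifted on the logit scale:

```
logit(p_pop) += cline_slope * z_pop
```

where `z_pop` is the population's standardized environmental value.
`cline_slope = 1.5` gives per-transect detection power ≥ 0.8 for a
top-1 %-of-|z| criterion at the default sample sizes, while leaving the
genome-wide statistic distribution recognizably null after genomic
control. Frequencies are clipped to `[1e-4, 1 − 1e-4]` before binomial
sampling so no site is forced monomorphic or fixed by the shift.

### Genotypes, sites, and missingness

Genes (`n_genes = 200`) carry `Poisson(snps_per_gene_mean = 5)` SNPs each
(minimum 1) laid out on autosomes plus a small sex-chromosome block that the
filtering stage is expected to drop. Genotype calls are
`Binomial(2, p_pop)` per individual; calls are masked missing completely at
random at `missing_rate = 0.05`, typical of RAD/exome data after QC.

### Phenotype

Body weight in grams is

```
y = baseline_weight + sex_effect·1[male] + Σ_k β_k g_k + ε
```

with `n_causal_snps = 10` causal loci, raw effects
`β ~ Normal(0, genetic_sd²)` (`genetic_sd = 1.5` g sets the per-allele
effect scale before heritability normalization), and `ε ~ Normal(0,
residual_sd²)`. The genetic scores are rescaled so the genetic fraction of
(genetic + residual) variance equals `h2` (default 0.3) exactly in the
realized sample; `h2 = 0` zeroes the genetic term, and `h2 > 0` with
`n_causal_snps = 0` is rejected. Sex alternates deterministically within
each population, so sex is exactly balanced and orthogonal to population.

### What the generator does and does not emulate

It reproduces the *statistical* structure the downstream methods consume:
hierarchical drift, environmental clines, polygenic phenotype, MCAR
missingness, exome-like gene blocks. It deliberately does **not** simulate
linkage disequilibrium from a coalescent or recombination map (sites are
conditionally independent given frequencies), demographic history beyond
the two-level clade/population hierarchy, genotyping-error structure, or
non-additive phenotype effects. LD pruning is therefore exercised on
hand-constructed fixtures, not on simulator output.

### Determinism

All randomness flows from a single `numpy.random.default_rng(seed)`;
identical configs give byte-identical fixture files (VCF/TSV/BED/JSON,
fixed float formatting).

## 2. Variant I/O and filtering (`variants_io`)

`GenotypeMatrix` stores an `(n, m)` int8 call matrix plus a site table
(chrom, pos, ref, alt, id) with positions strictly sorted within
chromosome — an enforced invariant. VCF reading uses `cyvcf2`; multiallelic
sites and indels are skipped with a warning. Filters: site MAF ≥ 0.05 and
call rate ≥ 0.8 *within every population* (a site failing in any one
population is removed, since downstream per-population frequencies would
otherwise be undefined or noisy); filtering is idempotent. LD pruning is
greedy within a sliding window on the squared Pearson correlation of
imputed dosages: earlier-position SNPs are kept, later SNPs with
`r² > threshold` against any kept SNP are dropped. SNP→gene assignment uses
half-open BED intervals `[start, end)`; a SNP may map to several
overlapping genes.

## 3. Population-genetic summaries (`popgen`)

* **π** is the average pairwise difference per site computed from allele
  counts with the unbiased `n/(n−1)` factor; **θ_W** divides the segregating
  site count by the harmonic number `a_n` and sequence length.
* **Hudson F<sub>ST</sub>** uses the ratio-of-sums ("ratio of averages")
  estimator with per-site numerator
  `(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)` and denominator
  `p₁(1−p₂) + p₂(1−p₁)`. Ratio of sums, not mean of ratios: it is the
  consistent estimator and the one with the Balding–Nichols expectation
  `F`.
* **PCA** is an eigendecomposition of the covariance of mean-imputed,
  centered dosages.
* **Isolation by distance** regresses pairwise genetic distance on
  great-circle (haversine, R = 6371.0088 km) distance between population
  coordinates.
* **Neighbor joining** implements the canonical Q-matrix algorithm.
  Because `Q[i,j]` and `Q[j,i]` can differ by 1 ulp in floating point
  (`((n−2)d − r_i) − r_j` is not evaluated symmetrically), the arg-min is
  searched over the strict upper triangle only, with deterministic
  tie-breaking on `(i, j)`. On additive distance matrices the recovered
  tree reproduces all path lengths to 1e-9 (verified against random trees
  and against Biopython's implementation for topology).
* **Bootstrap support** resamples sites with replacement; resampled
  indices are sorted before building the replicate matrix so the
  position-sortedness invariant holds (the distance depends only on the
  multiset of sites, so sorting changes nothing). Support is the percentage
  of replicate trees containing each internal bipartition, canonicalized
  against the leaf universe.

## 4. Environmental association (`envassoc`)

The scan is a latent-factor regression in the LFMM spirit: for each SNP,
OLS of mean-imputed centered dosage on `[1, env, U]` where `U` holds `K`
latent factors (default `K = 2`). The factors are the top left singular
vectors of the genotype matrix **after projecting the environmental
variable out of the sample space** (QR-based projection). Without that
projection the genome-wide cline — which is exactly the signal of
interest — would be absorbed into factor 1 and regressed away; with it,
the factors capture residual structure (for example, the between-transect
split) while leaving cline signal in the environment coefficient. This is
the ridge-LFMM construction. A constant or factor-collinear environment is
flagged with a warning, and the batched OLS uses a pseudoinverse so a
degenerate design still yields finite output.

**Genomic control.** λ<sub>GC</sub> = median(z²) / 0.4549 (the median of
χ²₁). Calibrated p-values are `chi2(1).sf(z²/λ)`. On simulator output the
raw statistics are inflated (λ ≈ 3 on two-transect data with K = 2; ≈ 1.1
on one-transect null data) because residual within-population correlation
beyond the K factors scales all statistics by a near-constant factor —
exactly the failure mode genomic control removes. The null guarantee of
the full method, verified in the tests, is uniformity of the *calibrated*
p-values.

**Multiple testing.** Benjamini–Hochberg q-values via
`statsmodels.stats.multitest.multipletests`. Outlier genes are genes with
at least `min_snps` SNPs at `q ≤ q_threshold`. `combine_runs` merges scans
of the same sites (for example, two MAF-filter settings) by the median z
per site, then recalibrates.

## 5. Mixed-model GWAS (`gwas`)

Kinship is the centered GCTA-style estimator
`K = Z Zᵀ / m` with `Z` the column-centered (and variance-standardized)
imputed dosages. Note `K 1 = 0`: centering annihilates the all-ones vector.

The LMM `y = Wα + xβ + u + ε`, `u ~ N(0, σ_g² K)`, `ε ~ N(0, σ_e² I)` is
fitted EMMA-style: eigendecompose `K` once, rotate `y`, `W`, `x` into the
eigenbasis, and profile everything but the variance ratio
`δ = σ_g²/σ_e²`, giving weights `1/(δ s_i + 1)`. δ is optimized per SNP on
a `log₁₀ δ ∈ [−5, 5]` grid (61 points) followed by bounded scalar
refinement (`scipy.optimize.minimize_scalar`). **REML is the default**
criterion for δ (flag `reml=False` switches the Wald fit to ML).

**Profile likelihood-ratio test.** The LRT always compares ML
log-likelihoods of the full and covariates-only models, both evaluated at
the SNP's own δ̂. Re-optimizing δ under the null by pure ML is ill-posed
here: because centered kinship annihilates the ones vector and the
intercept lies in the covariate span, the ML profile likelihood in δ drifts
as `−½ log δ` and its maximizer escapes to the grid boundary (REML's
`log det(Xᵀ H⁻¹ X)` term exactly cancels the drift, which is why REML is
the default for δ). Evaluating both likelihoods at the same per-SNP δ̂
yields the profile LRT `n·log(1 + t²/(n−q))`, a monotone function of the
Wald statistic per SNP — so Wald and LRT rankings agree exactly, and
p-values agree closely away from the extreme tail.

With `K = I` the model collapses to OLS exactly (verified coefficient- and
standard-error-wise against `numpy.linalg.lstsq`). δ is identifiable only
when `K` has appreciable eigenvalue spread; on unstructured kinship
(Marchenko–Pastur eigenvalues near 1) δ̂ is biased toward 0, which is a
property of the model, not the optimizer.

**Per-SNP variance explained.** With allele frequency `f`, effect `β`,
standard error `se`, and `N` diploid samples,

```
PVE = 2β²f(1−f) / ( 2β²f(1−f) + se²·2N·f(1−f) )
```

which lies in `[0, 1)`, is 0 at β = 0, and increases in |β|/se.
`gene_pve` sums single-SNP PVE over a gene's SNPs (an upper-bound style
summary that ignores LD between them).

## 6. Parallelism test (`parallelism`)

Given outlier sets A and B in a universe of G genes, the null hypothesis
is that A and B are independent uniform draws of their observed sizes. The
Monte-Carlo test draws, per replicate, random gene labels and takes the
overlap of the top-`n_a` and an independent top-`n_b` selection
(implemented with `argpartition` on random keys; each replicate is an exact
draw from the hypergeometric null, verified by exhaustive enumeration on
small universes and χ² goodness of fit on larger ones). Reported:

* `expected_perm` — Monte-Carlo null mean; its analytic counterpart is the
  hypergeometric mean `n_a·n_b/G` (`hypergeometric_oracle`).
* `p_perm` — add-one estimator `(c+1)/(n_perm+1)` where `c` counts
  replicates ≥ observed; never exactly 0, honest for rare events.
* `p_ci` — Wilson score interval for the exceedance probability
  (`statsmodels.stats.proportion.proportion_confint`).
* `hyper_tail_p` — the exact hypergeometric upper tail as a cross-check.

At the genome scale used in `scripts/acceptance.py`
(G = 24 336, n_a = 4438, n_b = 1859), the null mean is
4438·1859/24336 ≈ 339.01 genes and an observed overlap of 434 lies > 5 null
standard deviations above it (`p_perm ≈ 1e-5` at 100 000 replicates, exact
tail ≈ 5e-9).

## 7. Pipeline (`pipeline`, `cli`)

`run_pipeline` chains simulate-or-ingest → filter → diversity/structure →
per-transect environmental scan → outlier genes → overlap test → JSON
report, from a YAML config validated up front (`validate_config` rejects
unknown keys and configs that specify both a simulation block and an
ingest block, and names the offending file/key in its errors). Stages are
re-entrant: the run report records per-stage outputs and the same seed
reproduces the run exactly. The CLI (`click`) exposes `simulate`, `filter`,
`overlap`, and `run-all`.

## Problem sizes and runtime

Defaults are chosen so the full test suite runs in ~1–2 minutes and the
100 000-replicate genome-scale overlap test in well under a minute on one
core: the simulator's default dataset is 100 samples × ~1000 SNPs; LMM
fixtures use a few hundred to a few thousand SNPs; the statistical-power
and type-I-error checks use the smallest sample sizes at which the
asserted bounds are theoretically attainable (for example, null
genotype–phenotype |r| has expectation `√(2/π)/√(n−1)` under exact
independence, so a 0.05 bound needs n ≳ 500).

## Limitations

* No LD simulation; LD pruning is validated on constructed fixtures only.
* Missingness is MCAR; informative missingness is out of scope.
* The environmental scan models a single environmental variable; multi-
  variable designs require repeated scans plus `combine_runs`.
* `gene_pve` ignores LD between a gene's SNPs.
* The bootstrap resamples sites independently, which overstates support
  when sites are linked.
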