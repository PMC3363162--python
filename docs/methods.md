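# Methods

## Model

The trait model for the `n_p` phenotyped individuals is
`y = μ 1 + Z a + Σ_k X_k α_k + e` with

* `a ~ N(0, A σ²_a)` over all pedigree individuals, `A` the numerator
  relationship matrix;
* `α_k | δ_k ~ N(0, σ²_g0)` if `δ_k = 0`, `N(0, σ²_g1)` if `δ_k = 1`,
  `δ_k ~ Bernoulli(π1)`;
* `e ~ N(0, I σ²_e)`.

`σ²_g1 = r σ²_g0` with the ratio `r = 100` fixed throughout; the common
scale `σ²_g0` is a free parameter. `π0 = 1 − π1` has a `Beta(100, 1)`
prior, i.e. `π1 ~ Beta(1, 100)` with prior mean `1/101` — this
orientation is what makes the Bayes-factor prior odds `(1/101)/(100/101)`.
Each variance (`σ²_a`, `σ²_e`, `σ²_g0`) has a uniform prior on
`(10⁻⁸, 10·Var(y))` by default (configurable; explicit bounds are
required for prior-only runs, where `Var(y)` is undefined).

SNP design columns are allele counts, mean-centred over all genotyped
individuals (the intercept absorbs the shift; fitted values are
unchanged). A heterozygote-indicator dominance column per SNP can be
appended; it shares the same mixture prior rather than carrying an
independent one — one mixture keeps the sampler state simple and
dominance is off by default.

## Sampler

One cycle performs, in order:

1. **Mean** — Gibbs, flat prior: `μ | · ~ N(ȳ_res, σ²_e / n_p)`.
2. **Polygenic sweep** — single-site Gibbs in pedigree order using the
   sparse rows of `A⁻¹` (Henderson's rules with Meuwissen–Luo
   Mendelian-sampling variances, so inbreeding is handled in both `A`
   and `A⁻¹`). Individuals without phenotypes get prior-only
   conditionals and are still sampled, which is what propagates
   information to them for prediction.
3. **SNP pair sweep** — a fresh random partition of the SNPs into
   disjoint pairs each cycle. For a pair, the four indicator
   configurations are enumerated with the two effects integrated out
   analytically (marginalized Bernoulli; log-sum-exp for stability); a
   configuration is drawn, then the effects from the corresponding
   bivariate normal. Marginalizing the effects avoids the absorbing
   state that conditioning on the current effects would create. The 2×2
   system `V⁻¹ + X'X/σ²_e` is always positive definite (the prior
   precision is), so collinear or constant columns need no special
   path: a zero column simply reduces to a prior draw. An odd SNP count
   leaves one single-site update per cycle.
4. **Mixture proportion** — conjugate `π1 | δ ~ Beta(1 + Σδ, 100 + m − Σδ)`.
5. **Variances** — under a bounded uniform prior the full conditional of
   a variance with `k` contributing terms and quadratic form `S` is a
   scaled inverse chi-square with `k − 2` degrees of freedom, truncated
   to the bounds (rejection sampling with a clamped fallback; with no
   data it degenerates to the uniform prior, and `S = 0` pins the draw
   at the lower bound). Used for `σ²_a` (with `S = a'A⁻¹a`) and `σ²_e`
   (with the residual sum of squares).
6. **Mixture-variance scaling move** — Metropolis–Hastings: draw
   `f = exp(s·u)`, `u ~ U(−1, 1)`; propose `σ²_g0 → f σ²_g0`
   (and hence `σ²_g1 → f σ²_g1`) together with `α_k → √f α_k` for all k.
   With `σ²_g0` the single free variance, the transformation's Jacobian
   is `f^(1+m/2)` and the α-prior density ratio contributes `f^(−m/2)`,
   so the acceptance probability is `min(1, f · exp(−ΔSSE/(2σ²_e)))`
   plus the uniform-bounds check. The step size `s` is tuned during
   burn-in only (multiplicative Robbins–Monro toward acceptance 0.5 over
   100-proposal windows, clamped to [10⁻⁴, 5]) and frozen afterwards to
   preserve detailed balance. Polygenic effects are not rescaled by this
   move.

The residual vector and the SNP fit vector are maintained incrementally
and recomputed from scratch every 1,000 cycles; the maximum observed
drift is reported (typically ~10⁻¹³) and asserted < 10⁻⁸ in tests.

Correctness is established by three suites: conjugate toy problems with
closed-form posteriors; no-data (Geweke-style successive-conditional)
runs that must reproduce every prior marginal — the sharpest test of
the scaling move's Jacobian, since an error of `f^±1` shifts the
uniform-variance moments visibly; and agreement of the pair sampler
with the single-site sampler on a small problem.

Running posterior means of `δ_k`, `α_k` and `a_i` use every
post-burn-in cycle (unthinned); scalar draws are stored thinned
(default 10). Per-individual posterior-mean genetic values follow from
the means of `a` and `α` by linearity.

## Posterior summaries

* Heritability per stored cycle:
  `h² = (σ²_a + V_SNP) / (σ²_a + V_SNP + σ²_e)` with `V_SNP` the
  empirical variance of the fitted SNP genetic value across phenotyped
  individuals at that cycle. Both this "total" definition (default,
  since the model fits markers and polygenes jointly) and the
  polygenic-only ratio are available.
* HPD intervals by the sorted-window (shortest-interval) method.
* ESS as `n / (1 + 2Σρ̂_t)` with FFT autocorrelations accumulated in
  Geyer pairs until a pair sum turns non-positive; capped at `n`,
  NaN for a constant series.
* `BF = [p̂/(1−p̂)] / [π1/(1−π1)]` with prior `π1 = 1/101`; `p̂ = 1` maps
  to +inf, exported capped at 10⁶ with a flag. Classes: `BF > 10`
  significant, `3.2 ≤ BF ≤ 10` putative.
* QTL regions: per chromosome, greedy agglomerative clustering of
  classified SNPs on the genotype-correlation `r²` matrix. The
  published rule "r² of most SNP ≥ 0.7" is operationalized as
  average-linkage (mean cross-cluster `r² ≥ 0.7`; complete- and
  single-linkage selectable) with a maximum map gap of 0.1 Morgan
  between clusters. Grouping by LD can split or merge true QTL; that
  limitation is inherent to the rule and deliberately not "fixed".
* GEBV: posterior mean `a_i + Σ_k x_ik α_k` (total genetic merit; a
  SNP-only variant is a column selection away). Validation reports the
  Pearson correlation with simulated breeding values and the regression
  slope of truth on estimate.

## Synthetic data generator

The generator emulates the statistical structure of a three-generation
breeding design on simulated genomes: 20 sires × 10 dams each × 15
full-sib offspring (3,220 individuals), 9,990 equally spaced SNPs on
five 1-Morgan chromosomes, 10 of 15 offspring per family phenotyped,
parents never phenotyped, trait heritability 0.30.

* **Founder LD** — rather than replaying a long literal history, a
  population of 150 diploids starts at linkage equilibrium (per-locus
  allele frequencies uniform on (0.05, 0.95)) and random-mates for 200
  generations (Haldane recombination, crossovers ~ Poisson(map length),
  no mutation or selection), then expands to the founders. This
  produces map-distance-dependent `r²` and a drift-widened frequency
  spectrum including monomorphic and rare loci (which is what gives the
  QC filter real work); only the LD structure, not the literal history,
  is emulated.
* **Gene drop** — each non-founder receives one recombinant paternal and
  one recombinant maternal gamete; phase is retained so parent-of-origin
  effects are exact.
* **QTL architecture** (7 entries): one additive QTL on chromosome 1,
  two on chromosome 2, two linked in repulsion on chromosome 3 (0.04 M
  apart, equal and opposite effects, so positive LD between the loci
  cancels part of each marginal signal), one imprinted QTL on
  chromosome 4 (effect carried by the paternally inherited allele by
  default), and an additive×additive epistatic pair on chromosome 5
  (`effect · (g_A − 1)(g_B − 1)` on centred codes). Entries are placed
  at the nearest well-segregating SNP (founder MAF ≥ 0.15) to their
  requested positions. Relative effect weights default to
  (1.4, 1.0, 0.8, ±0.9, 0.9, 1.1).
* **Trait** — polygenic effects flow down the pedigree (founders
  N(0, s²); offspring = parent average + Mendelian sampling N(0, s²/2);
  parental inbreeding is ignored in the sampling variance, which is
  negligible in a three-generation design). QTL and polygenic parts are
  rescaled so the QTL explain 70% of the realized genetic variance
  (polygenic share 0.3 — the decomposition is not dictated by the
  emulated dataset's description, so it is a configurable default), and
  the residual variance is set from the realized genetic variance so
  that realized h² matches the 0.30 target (within ±0.03 sampling
  noise at n = 3,000).
* **Truth** — the recorded breeding value is the polygenic effect plus
  the least-squares projection of the total QTL genotypic value onto
  the causal allele counts (the classical average-effect definition);
  the genetic value additionally carries the imprinting and epistatic
  deviations.
* One master seed drives every stage through `SeedSequence`-derived
  child seeds; a dataset is bit-reproducible.

What the generator does **not** emulate: mutation, selection, sex
chromosomes, genotyping error, missing genotypes, family-size
variation. Passing tests therefore demonstrate correct inference under
the model's own assumptions with clean data — not robustness to the
artefacts of real genotyping pipelines.

## Problem sizes

The full-scale defaults (3,220 individuals / 9,990 SNPs / 52,000
cycles) match the emulated design. The package's "desk" preset — used
throughout the tests and the acceptance script — scales the design to
20 sires × 5 dams × 6 offspring (720 individuals, 400 phenotyped, 200
validation offspring), 350 SNPs per chromosome before QC (roughly
1,000 after), a 120-generation burn-in at population size 100, and
10,000-cycle chains. At this scale one replicate (simulation + chain)
takes a few seconds on one CPU with the numba kernel.

Scale matters for prediction accuracy: with 400 training phenotypes the
correlation between true and estimated breeding values of unphenotyped
offspring is around 0.55–0.75 (the mixture model consistently above a
GBLUP-style kinship regression on the same data), whereas designs with
thousands of training records support accuracies around 0.9. The
heritability posterior, in contrast, is already well calibrated at desk
scale (posterior means across seeds centred on the simulated 0.30).

## Numerical choices and edge cases

* δ-configuration probabilities via log-sum-exp; the 2×2 conditional is
  solved in closed form with an explicit Cholesky.
* Truncated variance draws: rejection against the untruncated scaled
  inverse chi-square (≤ 200 tries, then clamp); exact uniform draw when
  there is no data; lower-bound pile-up when the quadratic form is 0.
* Monomorphic-after-centering SNP columns, pairs of identical columns
  and `p̂ = 1` saturation all have defined behaviour (prior draw, still
  nonsingular system, capped BF with flag).
* Missing genotypes are mean-imputed per SNP with a warning.
* Chains abort with a diagnostic if a non-finite state is stored.
* `fit(..., update_*=False)` switches freeze individual blocks; they
  exist for validation and prior-only runs, not for routine use.

## Known limitations

* One chain per fit; no cross-chain convergence diagnostics (ESS and
  HPD are single-chain).
* The mixture is two-component only (no BayesA/B/R-style families).
* LD-block QTL grouping inherits the false-split/false-merge behaviour
  of the published rule.
* The polygenic variance mixes slowly relative to other parameters
  (ESS an order of magnitude lower), as is typical when markers and
  pedigree compete for the same variance.
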