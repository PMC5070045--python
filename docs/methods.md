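# Methods

## Liability-threshold ACE model

Each binary trait is the indicator that a standard-normal latent liability
exceeds a threshold; the prevalence `K` fixes the threshold at
`Φ⁻¹(1 − K)`.  Liability variance is partitioned into additive-genetic
(A), shared-environment (C) and unique-environment (E) proportions
(`a² + c² + e² = 1`; E also absorbs measurement error).  A pair of type
*s* has liability correlation `r_A(s)·a² + r_C(s)·c²`.  The default
relatedness map is

| pair type | r_A  | r_C  |
|-----------|------|------|
| MZ        | 1.00 | 1.00 |
| DZ        | 0.50 | 1.00 |
| FS        | 0.50 | 1.00 |
| MHS       | 0.25 | 0.83 |
| PHS       | 0.25 | 0.03 |

The half-sib shared-environment values reflect household co-residence
rates in Swedish censuses; both are configurable (`RelatednessMap`,
`relmap_overrides` in the CLI config), which is how sensitivity analyses
over alternative shared-environment assumptions are run.

Estimation maximizes the multinomial likelihood of the per-stratum 2×2
concordance tables.  Thresholds are free per pair-type stratum ("relaxed
thresholds"), accommodating prevalence differences between full and half
siblings.  Identifiability of a² against c² needs at least two strata with
distinct `(r_A, r_C)`; with fewer the fit warns and fixes c² = 0.

Parameterization: components are squared path coefficients normalized to
sum to one, with the E path pinned to raw value 1 so the map is locally
one-to-one — `a² = z_a²/D`, `c² = z_c²/D`, `e² = 1/D`,
`D = 1 + z_a² + z_c²`.  Non-negativity is automatic, and c² = 0 is the
smooth interior point `z_c = 0`, where the delta-method interval for c²
correctly collapses to zero width (the behavior seen in boundary fits of
real cohorts).

Optimization: Nelder–Mead from five fixed starting points, polished by
L-BFGS-B with finite-difference gradients (step 1e-6; the log-likelihood is
deterministic and smooth).  Convergence tolerance 1e-12 relative on the
objective.  A failed final line search at a point the derivative-free stage
already converged to is reported as convergence.

Confidence intervals: delta method from the observed information.  The
Hessian uses central differences with per-coordinate steps
`5e-4·max(1, |x|)`: for a log-likelihood of magnitude ~1e5, smaller steps
sit below the floating-point noise floor along weakly identified
directions and can produce indefinite curvature estimates (verified stable
across steps 1e-4 to 2e-3).  Boundary or flat information directions are
inverted as zero variance and flagged in `convergence["vcov"]`.

Small-sample behavior worth knowing: with a very rare trait (prevalence
~0.3%) the A-vs-C contrast is informed by a handful of concordant half-sib
pairs.  The constrained estimator then has a skewed sampling distribution:
whenever noise pulls ĉ² off its boundary, â² drops by about twice as much
(the full-sib correlation constrains `0.5a² + c²` tightly).  Point
estimates at such configurations should be read with the reported
intervals, and averages across replicates sit below the generating value
even though the median recovers it.

## Bivariate Cholesky decomposition

Two traits per person are modelled with lower-triangular 2×2 path matrices
per component (`A = a·aᵀ` etc.), guaranteeing positive semi-definite
component covariances.  After standardization to unit liability variances,
the within-person covariance is `A + C + E` and its off-diagonal entry —
the cross-trait tetrachoric correlation — decomposes additively as
`r = A₁₂ + C₁₂ + E₁₂`.  Cross-member blocks are `r_A·A + r_C·C`.  Trait
order is fixed (diagnosis first, outcome second) to match the temporal
logic of the design; the decomposition of `r` itself is order-invariant.

The likelihood is the 16-cell multinomial of the four dichotomized
liabilities per pair, per stratum, with per-stratum thresholds for each
trait.  Free parameters: trait-1 components (2), the second Cholesky row
normalized to unit length with the raw `e₂₂` entry pinned to 1 (5), and
`2 × strata` thresholds.

Starting values come from univariate fits of each trait's marginal tables
plus the pooled within-person cross-trait tetrachoric correlation
(attributed initially to A); optimization is coarse-to-fine L-BFGS-B — a
cheap integrator (256 points × 2 scramblings) absorbs most iterations, the
full-accuracy objective (512 × 4) polishes.  `p_E`, the test of the
unique-environment contribution, is a Wald test of the standardized E₁₂
entry via the delta method; under a purely genetic generating overlap it is
calibrated (p > 0.05 in the expected fraction of replicates).

## Normal rectangle probabilities

2-D rectangles use adaptive quadrature of
`∫ φ(x)·Φ((r·x − t₂)/√(1−r²)) dx` (absolute tolerance 1e-13): exact enough
for threshold regimes down to rare-disorder prevalences, and deterministic.

4-D rectangles use the Genz sequential-conditioning transformation
integrated with scrambled Sobol points under a fixed internal seed, so the
likelihood is deterministic and smooth in the parameters; the public
`orthant_probability_4d` doubles its point budget until an internal error
estimate (3× the scrambling s.e.m.) falls below the requested tolerance
(default 1e-6).  All 16 dichotomization patterns of a stratum are computed
in one batched call.  Tests cross-check the integrator against a dense
tensor-product Gauss–Legendre oracle and an independent QMC implementation.

## Familial aggregation

Concordance summaries report, per pair type, the share of pairs with at
least one affected member and the share with at least one deprived member,
split by affectedness, with Wilson binomial intervals.  Odds ratios come in
two orientations: own affection → own deprivation, and proband affection →
relative's deprivation.  Pairs with both members affected contribute both
orientations (double entry); covariate-adjusted variants use logistic
regression with cluster-robust (by pair) standard errors, covariate-free
variants the Woolf log-odds interval with Haldane–Anscombe correction for
empty cells.  With double entry the Woolf interval treats entries as
independent and is mildly anticonservative when traits are familially
correlated; under independence its coverage is nominal (checked in tests).

## Polygenic scores

Scores are `Σ β_j·d_ij` over SNPs at or below the discovery p-value
threshold (inclusive), after aligning genotype coding to the effect allele
(dosage reflected when alleles are swapped; irreconcilable SNPs dropped and
counted; optional removal of strand-ambiguous A/T–C/G SNPs for real data).
Missing dosages are mean-imputed (2× sample allele frequency).  Incremental
R² is the R² difference between the covariates+score and covariates-only
linear models — identical to the squared semi-partial correlation — with
the score coefficient's t-test p-value.  No LD clumping is implemented: the
intended weight sets are already pruned to approximate linkage
equilibrium.

## Synthetic data

The generators produce exactly the structures the estimators assume:

* Pair cohorts draw 2-D (univariate) or 4-D (bivariate) normal liabilities
  from the model-implied correlation matrices and dichotomize at
  prevalence-matched thresholds.  Default study conditions mirror the
  published designs: sibling cohorts of 592 009 FS / 68 684 MHS / 82 913
  PHS pairs with 11% (deprivation) and 0.3% (schizophrenia) prevalences;
  twin designs with 3% (psychotic experiences) and 25% (deprivation at the
  75th-percentile definition) prevalences.
* Deprivation dichotomization flags scores strictly above the empirical
  percentile (lower order statistic), so ties at the cutoff are never
  flagged; the synthetic continuous score is standard normal by assumption.
* `select_pairs` reproduces the cohort-construction rule: per family, the
  oldest two siblings born within five years, classified FS/MHS/PHS by
  shared parents.
* Genotype cohorts draw independent Binomial(2, p) allele counts (MAF
  uniform on a configurable range; float32 to keep the matrix small), with
  effect sizes scaled so the true score explains a target share of outcome
  variance (default 0.0015 at n = 6796, m = 5000, ten PCs explaining 0.02
  jointly).  Discovery p-values are uniform and independent of effects,
  with the smallest forced below 0.01 so every conventional threshold
  selects a non-empty set.

One root seed feeds deterministically spawned child streams per pair type
and per component, so identical seed + configuration yields byte-identical
cohorts.

What the simulations do **not** emulate: covariate effects on thresholds
are generated as zero by default (sex and birth year are emitted but
inert — enabling them shifts thresholds linearly on the probit scale);
no assortative mating, no linkage disequilibrium, no censoring by death or
emigration, no diagnostic misclassification, and the deprivation score has
no spatial or temporal autocorrelation.  Passing recovery tests therefore
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to their violation in real registries.

## Problem sizes in the test suite

Recovery tests run at the published sample sizes, including the
20-replicate calibration of the bivariate Wald test.  Running that
calibration at reduced pair counts is not sound: with a rare first trait
the A/C/E attribution surface becomes multimodal below roughly half the
registry size, and maximum likelihood then lands in a qualitatively wrong
basin on a sizeable fraction of replicates — an instructive failure mode
for anyone adapting the design to smaller cohorts.
Recovery of rare-trait heritability is asserted on means over
8–10 simulated registries because single-registry estimates carry sampling
noise comparable to the recovery tolerance (see the boundary-skew note
above).  The parametric-bootstrap check of the delta-method intervals uses
400 replicates of a 4000+4000-pair twin design.
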