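# Methods

## The model

The package analyses a binary wing-morph phenotype (1 = long-winged,
0 = short-winged) measured on offspring of a full-sib half-sib breeding
design, reared in cages at nymphal densities 1–12. Two Bayesian
threshold-trait ("animal") models are implemented, both with a Bernoulli
likelihood and logit link on a latent liability:

**Random-intercept (basic) model**

    y_i ~ Bernoulli(p_i)
    logit(p_i) = alpha + beta x_i + c_i + a_i + e_i
    c ~ N(0, V_C),  a ~ N(0, V_A A),  e ~ N(0, V_R), V_R = 1

**Random-slope (G×E) model**

    logit(p_i) = alpha + (beta + a_{i,2}) x_i + c_i + a_{i,1} + e_i
    (a_1, a_2) ~ MVN(0, G ⊗ A),  G = [[V_A,I, C_A,IS], [C_A,IS, V_A,S]]

Here x_i is nymphal density centred at 6.5 (the midpoint of 1–12), c_i a
cage (shared early-environment) effect, A the additive relatedness matrix
from the two-generation pedigree (0 / 0.25 / 0.5 off-diagonal for
unrelated, half-sib and full-sib pairs when founders are unrelated and
non-inbred), and e_i an individual latent residual whose variance is fixed
to 1 to anchor the liability scale. The relatedness matrix is computed by
the general recursive (tabular) method, so multi-generation pedigrees with
inbreeding are handled; the two-generation design values are the special
case tested against a gene-dropping Monte-Carlo oracle.

## Priors

Fixed effects carry improper flat priors. Each standard deviation
(cage, genetic intercept, genetic slope) carries a half-Student-t prior
with 3 degrees of freedom and a scale adjusted to the standard deviation
of the link-scale working response, floored at 2.5. These priors are
realized through the Huang–Wand (2013) hierarchical construction
(inverse-gamma mixtures, and for the 2×2 genetic covariance an
inverse-Wishart mixture with ν = 3), which keeps every conditional
conjugate while giving *exactly* half-t(3) marginals on the standard
deviations. The implied prior on the genetic intercept–slope correlation
is proper and symmetric about zero but mildly non-uniform; with ν = 2 it
would be exactly uniform, and we preferred matching the stated half-t
degrees of freedom. At the sample sizes involved these weak priors have
negligible influence except to regularize separation.

## Sampling

The posterior is sampled by Pólya-Gamma data augmentation: conditional on
ω_i ~ PG(1, η_i), the Bernoulli-logit likelihood is Gaussian in the linear
predictor, so fixed effects, cage effects, the latent residual, the
breeding values (single-site bivariate updates against the sparse
precision A⁻¹, inverted blockwise over pedigree connected components) and
all variance components have closed-form updates. PG(1, z) variates are
drawn with the exact Devroye alternating-series rejection sampler — no
truncated-series approximation — validated in the test suite against the
PG mean formula and the closed-form Laplace transform.

Centered-parametrization Gibbs samplers mix notoriously slowly for
variance components, so each sweep ends with interweaving moves:

- exact translation moves shuttling location between the intercept and
  each zero-mean random field (cage, residual, genetic intercept; and the
  population slope with the genetic slope field), valid as Gibbs moves
  under the flat fixed-effect prior;
- ancillarity–sufficiency rescaling of each standard deviation: the field
  is whitened, a Gaussian proposal is drawn from the whitened likelihood,
  and acceptance depends only on the conditional prior ratio;
- an exact Gibbs update of the regression coefficient of the slope field
  on the intercept field, whose conditional prior under the
  inverse-Wishart mixture is Gaussian — this is what moves C_A,IS.

These moves raise effective sample sizes by one to two orders of
magnitude at no measurable cost. The whole chain runs as a single
numba-compiled kernel (~2 μs per individual-sweep), seeded explicitly, so
results are bit-reproducible.

Chain-length presets: `desk` (2 chains × 2,000 warmup + 4,000 sampling,
thin 2) for interactive use; `paper` (2 × 50,000 + 120,000, thin 70)
reproduces the published protocol; `fast` for permutation fits.
Convergence is reported as rank-normalized split R̂ and bulk ESS (via
ArviZ) with default thresholds R̂ ≤ 1.01, ESS ≥ 400.

Sampler correctness is established by (i) a brute-force Gauss–Hermite
quadrature oracle — the full grid posterior of a 30-individual
intercept-only toy problem, against which posterior means agree within
0.1; (ii) parameter recovery: at the published posterior-median generative
values and n ≈ 4,000, each generative value falls inside its own 95% HPD
interval in ≥ 8 of 10 seeded replicates; and (iii) nesting: with the slope
variance pinned to zero, the random-slope code path reproduces the basic
model's posterior (KS < 0.1).

## Variance decomposition

On the link scale the phenotypic variance is V_F + V_A + V_C + V_R + π²/3,
with V_F = β²V_x the fixed-effect (density) variance and π²/3 the
distribution-specific variance of the logit. For the random-slope model
the additive term is the **marginalized** additive variance

    V_A,M = V_A,I + V_A,S·V_x + μ²·V_A,S + 2μ·C_A,IS,

with μ, V_x the mean and variance of the centred density over phenotyped
individuals; the slope-exclusive part is V_S = V_A,S(V_x + μ²). Because
the convention for the published proportions is ambiguous, the raw ratios
V_A,I/total and V_A,S/total are also reported, explicitly labelled. All
proportions are computed per posterior draw and summarized by medians and
95% HPD intervals (shortest-interval definition), not as ratios of
medians.

Conditional on a density x, V_A(x) = V_A,I + 2x·C_A,IS + x²·V_A,S and the
link-scale conditional proportion is V_A(x)/(V_A(x) + V_C + V_R + π²/3).
The data-scale (observation-scale) variant multiplies each link-scale
component by the squared derivative of the inverse link — the squared
logistic density at the fitted linear predictor α + βx per draw — and
uses the Bernoulli observation variance P(1−P), with P the *average*
long-winged proportion, in the total. Using the average P (rather than a
density-specific p(x)) in the observation term is what produces the
interior maximum of the heritable share at moderate densities; with the
density-specific p(x) the quadratic growth of V_A(x) toward low densities
dominates and the maximum sits at the boundary. The overall data-scale
decomposition uses the same delta-method factor at logit(P).

## Randomization test for the G×E variance

Posterior mass of a variance component is bounded away from zero even
under a true null, so the slope variance is judged against a permutation
reference: the real model is fitted once; then for each of 19 permutations
of the density vector, a model is fitted that keeps the real density as a
fixed effect and the pedigree random intercept, while the permuted density
enters as an additional fixed effect and as the random-slope covariate.
The comparison statistic is the posterior median of V_A,S; the verdict is
significant at the 95% (19/20) level when the real statistic strictly
exceeds all 19 null statistics. Permutations are individual-level by
default; a cage-blocked variant (cage-level densities shuffled between
cages) is available, since cage-constant covariates are arguably the more
faithful null for this design. Null fits may run at cheaper MCMC settings
than the real fit: Monte-Carlo noise in a null median only inflates the
maximum the real statistic must beat, which is conservative for the
type-I error, whereas the real fit's median must be estimated well — at
very short chains the real median's noise is what produces spurious
significance.

A genuine small-sample caveat surfaced during calibration: below roughly
800 phenotyped individuals the individual-level permutation null becomes
anticonservative. The real covariate is constant within cages, so the
real fit identifies slope variance more weakly than a null fit whose
permuted covariate varies within cages; the real posterior then leans
more on the prior and its median sits systematically higher than the
null medians. Larger samples (or the cage-blocked permutation variant)
restore nominal behaviour; the bundled calibration check therefore runs
at n ≈ 800–1,000, the smallest size at which the procedure held its
nominal 5% level in our sweeps.

## Synthetic data generator

The generator reproduces the study conditions: 68 sires each mated to 1–4
dams (uniform); Poisson (mean 6, truncated ≥ 1) egg pods per dam that
yield at least one hatchling; one pod = one cage; 25% early mortality
(uniform within cage, applied before splitting); cages whose survivor
count exceeds 8 are split evenly into a source and a receiving cage (odd
counts differ by one), except for a 25% non-compliant fraction left
unsplit — the route by which nymphal densities 9–12 arise, mirroring the
32 unsplit high-density cages of the study. Density definitions follow
the study: embryo density = hatchlings of the pod; hatchling density =
pre-split cage count (missing for receiving cages); nymphal density =
post-split, post-mortality count. The pod hatchling-count distribution
over 1–12 was calibrated once, by penalized least squares with
moment-matching constraints on the expectation of the
mortality-and-splitting pipeline, to reproduce the right-skewed
nymphal-density marginals (modal density 5, max class-share error ~2%)
and the study's covariate moments exactly (nymphal-density mean 5.21 and
variance 5.06, i.e. centred moments μ ≈ −1.29, V_x ≈ 5.06).

Phenotypes follow the random-slope liability model, with generative
defaults equal to the published posterior medians (α = 1.146, β = 0.589,
V_C = 0.572, V_A,I = 1.485, V_A,S = 0.191, C_A,IS = 0.183, V_R = 1).
Breeding values are sampled pedigree-recursively (founders ~ MVN(0, G),
offspring = parental mean + MVN(0, G/2) Mendelian deviation), which
realizes MVN(0, G ⊗ A) exactly for this design. Sex is assigned 50:50
independently of morph. Latent η and p are attached to the output for
diagnostics.

Not emulated: hatching cohorts (a husbandry, not statistical, unit),
maternal fecundity–density correlation (r = 0.33 in the study), the 6%
of nymphs lost to causes other than death, and multi-pod cages. Passing
tests on these synthetic data therefore demonstrate correctness of the
estimation machinery under the stated generative model, not robustness
to those real-data complications.

## Problem sizes and numerical choices

Desk-scale defaults keep the full test suite and the acceptance script
within interactive budgets: recovery runs 10 replicates at n ≈ 3,300–4,400
phenotyped with 2 × (800 + 1,600) sweeps; the randomization-test
calibration uses 20 repetitions at n ≈ 650 and its power check 10
repetitions at n ≈ 1,300 (scaled-down study sizes); the quadrature oracle
uses n = 30 with a three-parameter grid (the genetic term unstructured,
A = I) and a reduced, fixed prior scale of 1.0 so that posterior means
are not dominated by the heavy half-t tails that weakly identified
variance components otherwise produce. HPD intervals use the
shortest-interval definition on pooled draws. Degenerate inputs
(constant covariate, complete separation, single chains, zero-margin
tables) are rejected or warned about explicitly rather than silently
accepted.

## Known limitations

- Founders are assumed unrelated and non-inbred; genomic relatedness and
  inbreeding coefficients are out of scope (the tabular A itself handles
  inbred pedigrees).
- One covariate, Bernoulli responses only; no dominance, maternal genetic
  effects, or model comparison.
- The published-table-style percentage decomposition depends on a convention
  (which additive term enters the total); both conventions are reported
  and labelled rather than adjudicated.
- Single-site breeding-value updates mix adequately only together with
  the interweaving moves; chain-length defaults assume them.
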