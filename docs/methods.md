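# Methods

## The model

`twinmeth` decomposes individual differences in DNA methylation — one CpG
site at a time — into genetic and environmental sources, using same-sex twin
pairs measured at two occasions roughly a decade apart. The phenotype is the
M-value, `M = log2(beta / (1 - beta))`, whose roughly unbounded scale suits
variance modelling better than the bounded methylated fraction (beta).

A pair contributes a 4-vector in slot order
`(twin1_t1, twin1_t2, twin2_t1, twin2_t2)`, modelled as multivariate normal.
Three latent sources build the covariance:

* **A** — additive genetic effects, shared 100% by MZ co-twins, 50% (in
  expectation) by DZ co-twins;
* **C** or **D** — common (family) environment, shared fully by both
  zygosities, *or* genetic dominance, shared 100% by MZ and 25% by DZ
  co-twins. C and D cannot be estimated simultaneously from twin pairs
  alone, so ACE and ADE variants are fitted separately;
* **E** — non-shared factors (person-specific environment, measurement
  error), never shared within a pair.

Each source has a 2×2 lower-triangular Cholesky factor across the two
occasions, `L = [[l11, 0], [l21, l22]]`, contributing `L L'` to the
within-person 2×2 covariance — positive semidefinite by construction. The
occasion-1 variance of a source is `l11²`; the occasion-2 variance is
`l21² + l22²`; the cross-occasion covariance is `l11·l21`. The cross-twin
block multiplies A by 1 (MZ) or 0.5 (DZ), D by 1 or 0.25, C by 1, E by 0.

Two cohorts are pooled: the second ("country 1") may differ in scale, so
free per-occasion SD scalars `k1, k2` pre/post-multiply its 4×4 covariance
via `diag(k1, k2, k1, k2)`; country 0 is the reference (scalars 1).
Standardized shares are invariant to the scalars, which cancel in ratios.

Means are linear in covariates: per-occasion intercepts plus age (each
individual's age at that occasion, centered at 74 years), sex (0 = male,
1 = female) and country (0/1). By default the age/sex/country slopes are
shared across occasions — the parsimonious, identifiable choice at ~100
pairs — with occasion-specific slopes available as a switch.

**Likelihood.** Full-information maximum likelihood: each pair contributes
the Gaussian log-density of exactly its observed slots (mean/covariance
restricted to the observed index set). Pairs in which one twin was measured
at a single occasion are therefore retained without imputation.

## Estimation

Five variants are fitted per site: ACE, ADE and the nested AE, CE, E
submodels. Free parameters are the source paths (9 for a full variant, 6
for AE/CE, 3 for E), the cohort scalars (when both cohorts are present) and
the mean coefficients (sex and country coefficients are dropped when the
corresponding covariate does not vary). Optimization is L-BFGS-B over a
bounded parameterization: diagonal paths ≥ 0 (a sign convention — the
likelihood is invariant to flipping a whole factor column), a floor of 1e-6
on the E diagonals to keep the covariance invertible, and `k1, k2` in
[1e-3, 1e3].

Starts: a moment-based start (OLS for the means; Falconer-style allocation
of twin covariances into source variances, with the phenotypic cross-time
covariance split proportionally to variance shares) plus, by default, two
random perturbations of it; submodel fits also warm-start from projections
of the fuller fits. Gradients are forward finite differences evaluated in a
single batched pass: all perturbed parameter vectors are pushed through one
stacked Cholesky/solve per observation group (observations are grouped by
zygosity × country × missingness pattern), which makes a 500-pair fit take
well under a second.

**Model comparison.** ADE is retained as "best" if its AIC is as good or
better than ACE's (ties retain ADE); a non-converged fit loses to a
converged one, and a site where neither full variant converged is flagged.
Nested comparisons use likelihood-ratio chi-square tests with df equal to
the difference in free-parameter counts: full vs E has df = 6, AE vs E has
df = 3, and the *stability* test — refitting the best variant with all
three cross-occasion paths `a21 = c21/d21 = e21 = 0` — has df = 3.
Reference distributions are the naive chi-squares at those dfs, with no
boundary-mixture correction, matching how such twin analyses are
conventionally reported; a mixture option exists but is off by default.
P-values are reported raw and thresholded downstream (1e-7, 1e-2, .05,
.01); no multiplicity correction is applied.

**Probe filter.** After fitting, sites whose model-implied moments are
implausible on the M-value scale are flagged: implied mean outside
[−6.25, 6.25] or implied SD strictly above 1.5, under either full variant
at either occasion. Implied means are evaluated at reference covariates
(age 74, sex at the sample mean, country 0) and SDs on the country-0 scale;
a raw-sample-moment variant of the filter is available as a switch.

## Derived quantities

* Standardized components per occasion (`std = abs / total`, country-0
  scale); broad-sense heritability is A + D under ADE and A alone under ACE
  (C is environmental).
* Cross-time etiologic correlations from the paths:
  `r = l11 l21 / sqrt(l11² (l21² + l22²))` per source, undefined (and
  flagged) when a source has zero variance at either occasion. Fisher-Z
  transforms clip |r| at 1 − 1e-6 (clipped sites flagged, excluded from
  Z-scale regressions).
* Classifications: *low stability* = stability-test p > .01 and E below 50%
  of total variance at one or both occasions, on the best variant;
  *E-dominated* = E above 99% at both occasions, with empirical MZ/DZ
  twin-correlation diagnostics (negative MZ correlation, DZ below −0.05,
  MZ − DZ below −0.1 at both occasions) computed on pairwise-complete
  observations.
* Across-site summaries (means/SDs per component for the all-ADE, ADE-best,
  all-ACE, ACE-best groups), a within-site paired t test of the occasion
  change in heritability, and Pearson correlations between implied SD and
  heritable share.

## Set comparisons

Per-site estimates at both occasions feed a random-intercept linear mixed
model (site = grouping factor): fixed effects are an intercept, an occasion
indicator and category codes (island relation, set membership), with
between-site and within-site variance components estimated by ML (not REML,
so Wald tests on fixed effects are coherent across fits; estimation is
delegated to statsmodels MixedLM, with an exact OLS fallback when the
between-site variance hits the zero boundary and leaves the Hessian
singular). The Wald chi-square jointly tests the category coefficients
(df = categories − 1) and ρ = σ²_between / (σ²_between + σ²_within)
measures how site-specific the estimates are across time.

Fisher-Z cross-time correlations are compared between groups by skew-normal
regression (location linear in the group indicator, free scale and shape),
fitted by direct ML over the scipy skew-normal density. The direct
parameterization has a flat score in the shape at 0, so the optimizer runs
from several shape starts (0, ±3) and keeps the best likelihood; at shape
0 the fit coincides with normal-error regression exactly. Group means on
the Z scale include the skew-normal mean offset `scale·δ·sqrt(2/π)`,
δ = shape/sqrt(1+shape²), and are inverse-transformed to correlation units
by tanh. A normal-error fallback (flagged) covers non-convergence.

Set overrepresentation uses the upper-tail hypergeometric test
`P(X ≥ k)` for an overlap of k between a target set of size K and a query
of size n in a universe of N, with fold enrichment `k/(Kn/N)`.

## The synthetic-data generator

The generator emulates the two-cohort aging-twin design the analysis
targets: a reference cohort of 22 MZ + 31 DZ pairs (53% female, occasion-1
age Normal(62.9, 7.2), gap Uniform(8.00, 11.82) years, 4 pairs with one
twin observed at a single occasion) and a scaled cohort of 18 MZ + 25 DZ
pairs (72% female, age Normal(76.2, 1.8), SD scalars k1 = 0.90, k2 = 0.88).
Sites are drawn independently from the model-implied multivariate normal
given per-site truth paths; per-site seeds spawn reproducibly from a master
seed. The default methylome truth sampler draws per-site standardized
shares from Dirichlet distributions with means (0.111, 0.127, 0.762) at
occasion 1 and (0.091, 0.089, 0.820) at occasion 2 and concentration 4
(matching the across-site mean/SD structure such data exhibit), strong
genetic cross-time correlations (0.97) against weak non-shared ones (0.20),
log-normal total SDs around 0.35, and occasion means in the typical bimodal
M-value range.

What it does **not** emulate: probe-level array artifacts, batch effects,
cell-composition signal (removed upstream in real pipelines), non-Gaussian
site distributions, or dependence between nearby CpGs. Passing recovery
tests therefore demonstrates correctness of the estimator under the model's
own assumptions, not robustness to real-data violations of them.

## Validation-study problem sizes and numerical choices

* Parameter recovery: 200 sites × 500 pairs (250 MZ + 250 DZ, one cohort),
  fixed truth shares (0.10, 0.13, 0.77) at both occasions with strong
  genetic cross-time correlation (0.97); mean fitted occasion-1 components
  recover the generating values within 0.03. Per-site A/D estimates are
  individually noisy (the two sources are strongly anti-correlated in the
  sampling distribution and truncated at zero variance, so single-site A/D
  splits should not be over-interpreted); the aggregate means carry a small
  net upward A+D truncation bias at this n that shrinks with sample size.
* Stability-test calibration: 400 sites × 600 pairs under cross-paths-zero
  truth. At a few hundred pairs the naive df = 3 LRT is slightly liberal
  (mean chi-square ≈ 3.14 at 300 pairs, a Bartlett-type finite-sample
  inflation); 600 pairs sit close enough to the asymptotic regime (mean
  chi-square ≈ 2.93, rejection ≈ 0.05). At the 96-pair study scale the
  same test is therefore expected to run slightly anti-conservative.
* Cross-time correlation oracle: path formula vs the empirical correlation
  of 2×10⁷ simulated latent-score pairs, 50 random parameter draws; the
  Monte-Carlo SE (≤ 2.3e-4) keeps the 1e-3 agreement band meaningful.
* Mixed-model recovery: ρ within 0.05 at 2000 sites; skew-normal group
  shifts recovered within 0.03 in correlation units.
* Optimizer tolerances: L-BFGS-B `gtol` 1e-8, `ftol` 1e-12, forward-
  difference step 1.5e-7·max(1, |x|). Ties in ACE/ADE selection go to ADE
  by rule. Degenerate inputs (a site with < 2 pairs, all-identical
  responses, empty set intersections) raise explicit errors rather than
  returning silent results.

## Known limitations

* Point estimates and tests only: no standard errors or confidence
  intervals on variance components.
* Two occasions, same-sex pairs; no sex-limitation or more-than-two-wave
  models.
* The naive chi-square references ignore boundary mixtures (by design, to
  match conventional practice); the full-vs-E test is conservative under
  E-only truth.
* Real-data artifacts (batch, cell composition, probe cross-reactivity)
  are assumed removed upstream.
* Classification flags are computed independently per site; regularities
  between them (e.g. E-dominated sites rarely reaching epigenome-wide
  familial significance) are empirical properties of data, not enforced
  constraints.
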