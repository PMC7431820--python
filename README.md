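# twinmeth

Bivariate Cholesky twin models for longitudinal DNA methylation.

`twinmeth` is for quantitative geneticists and epigenomics researchers who
want to ask, CpG site by CpG site, *why* people differ in DNA methylation
and why those differences persist or change across a decade of aging. Given
same-sex monozygotic (MZ) and dizygotic (DZ) twin pairs measured at two
occasions, it decomposes M-value variance at each site into additive
genetic (A), common-environment (C) or dominance (D), and non-shared (E)
sources, and decomposes the *covariance across occasions* into the same
sources — separating the contributors to stability from the contributors to
change.

## The model

For a pair, the four measurements `(twin1_t1, twin1_t2, twin2_t1, twin2_t2)`
are multivariate normal. Each source has a lower-triangular 2×2 Cholesky
factor across occasions, `L = [[l11, 0], [l21, l22]]`, contributing `L Lᵀ`
to the within-person covariance; cross-twin blocks scale A by 1 (MZ) or 0.5
(DZ), D by 1 or 0.25, C by 1 for both, and E by 0. Free scalars `k1, k2`
absorb per-occasion SD differences between the two cohorts, and means are
adjusted for age (centered at 74), sex and country. Fitting is
full-information maximum likelihood — each pair contributes the density of
exactly its observed slots, so twins with a single measured occasion are
retained.

Per site, ACE, ADE, AE, CE and E variants are fitted; ADE is retained as
best when its AIC is as good or better than ACE's. Likelihood-ratio tests
probe familial signal (full vs E, 6 df; AE vs E, 3 df) and cross-time
stability (all cross-occasion paths zero, 3 df). Fitted paths are
transformed to standardized components, broad-sense heritability (A + D
under ADE, A under ACE), and cross-time etiologic correlations
`r = l11·l21 / √(l11²(l21² + l22²))` with Fisher-Z transforms. Set-level
questions (island vs shore vs open sea, epigenetic-clock sites vs
background) use random-intercept mixed models over both occasions'
estimates with Wald χ² tests and the intraclass ratio ρ; Fisher-Z
correlations are compared between site groups by skew-normal regression;
set overrepresentation uses the upper-tail hypergeometric test.

A synthetic-data module generates twin cohorts emulating the two-cohort
Scandinavian aging-twin design (53 + 43 pairs, ~10-year gap, cohort SD
scalars 0.90/0.88, a few single-occasion twins) with per-site truth tables
for parameter-recovery studies. See `docs/methods.md` for assumptions,
parameter defaults and validation-study sizes.

## Worked example

```python
import twinmeth as tm

# two-cohort design: 53 + 43 same-sex twin pairs, two occasions ~10 y apart
cohort = tm.default_cohorts(seed=0)

# one CpG whose variance is 30% additive-genetic, 20% dominance, 50% non-shared
truth = tm.params_from_components(
    shares_t1=(0.30, 0.20, 0.50), shares_t2=(0.25, 0.20, 0.55),
    total_var_t1=0.16, total_var_t2=0.18,
    r_sources=(0.97, 0.97, 0.20), second_source="D",
    k1=0.90, k2=0.88, beta0_t1=2.0, beta0_t2=2.1,
)
records = tm.simulate_site(tm.SiteTruth("cg_demo", truth, "ADE"), cohort, seed=11)

fit = tm.fit_variant(records, "ADE", tm.FitSettings(seed=5))
comp = tm.standardize(fit)
corr = tm.cross_time_correlations(fit)
print(f"loglik = {fit.loglik:.2f}, AIC = {fit.aic:.2f}, converged = {fit.converged}")
print(f"occasion-1 shares: A = {comp.std_A_1:.3f}, D = {comp.std_CD_1:.3f}, E = {comp.std_E_1:.3f}")
print(f"broad heritability: {comp.broad_h2_1:.3f} (t1) -> {comp.broad_h2_2:.3f} (t2)")
print(f"cross-time correlations: rA = {corr.rA:.2f}, rE = {corr.rE:.2f}")

e_fit = tm.fit_variant(records, "E", tm.FitSettings(seed=5))
chi2, df, p = tm.lrt(fit, e_fit)
print(f"familial signal (ADE vs E): chi2({df}) = {chi2:.2f}, p = {p:.4f}")
```

Output:

```
loglik = -118.05, AIC = 268.11, converged = True
occasion-1 shares: A = 0.057, D = 0.484, E = 0.458
broad heritability: 0.542 (t1) -> 0.397 (t2)
cross-time correlations: rA = 1.00, rE = 0.25
familial signal (ADE vs E): chi2(6) = 15.14, p = 0.0192
```

At 96 pairs the A/D split is noisy (the two are barely separable — broad
heritability A + D is the stable quantity: 0.54 fitted vs 0.50 generated at
occasion 1), the genetic cross-time correlation is estimated as perfect
while the non-shared one is weak (generated: 0.97 and 0.20), and the 6-df
test correctly detects familial signal at this moderately heritable site.

The same flow runs from the shell:

```bash
twinmeth simulate --out-dir run --n-sites 100 --seed 7
twinmeth fit --data run/methylation.tsv --pairs run/pairs.tsv --out run/results.tsv --seed 7
twinmeth classify  --results run/results.tsv --out run/classifications.tsv
twinmeth summarize --results run/results.tsv --out run/summary.tsv
twinmeth demo --out-dir demo_run --n-sites 200 --seed 7   # everything at once
```

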