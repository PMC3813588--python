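# Methods

## Estimands and model

**Relative concentration index (RCI).** For outcome y (the age-standardized
cognitive z-score), normalized weights w (Σw = 1) and weighted fractional
ranks R in the log per-capita-expenditure (log-PCE) ordering,

    C = (2/μ) Σᵢ wᵢ yᵢ (Rᵢ − ½),        μ = Σᵢ wᵢ yᵢ.

Ranks are midpoints of the cumulative normalized weight after a stable sort
by log-PCE: Rᵢ = Σ_{j<i} w̃ⱼ + w̃ᵢ/2. Tied ranking values keep their own
cumulative-weight rank in stable input order by default; a tie-averaging
option replaces ranks within a tie group by their weight-weighted mean.
Both conventions keep the weighted mean rank at exactly ½, which is what
the downstream algebra requires. Because the z-score takes both signs, the
index is not confined to [−1, 1]; no bounded-outcome rescaling (Erreygers
or Wagstaff normalization) is applied, and |μ| < 1e-6 triggers a runtime
warning since the relative index degenerates as the mean approaches zero.

**Delta-method SE.** The Kakwani–Wagstaff–van Doorslaer estimator with
weighted sums:

    var(C) = (1/n_eff) [ Σᵢ wᵢ aᵢ² − (1 + C)² ],
    aᵢ = (yᵢ/μ)(2Rᵢ − 1 − C) + 2 − q_{i−1} − qᵢ,

with qᵢ the cumulative weighted outcome share up to rank i and
n_eff = (Σw)²/Σw² the Kish effective sample size. At equal weights
n_eff = n and the classical unweighted formula is recovered; with raw 1/n
the variance is understated by the design effect (measured on 1000 null
replicates with gamma weights of CV ≈ 0.4: 92.5% coverage of the nominal
95% interval instead of ~95%). Confidence intervals are normal-
approximation, estimate ± z_{α/2}·SE. A nonparametric bootstrap SE is
provided as a cross-check utility only. A negative computed variance
(numerically possible in degenerate cases) is clipped to zero with a
warning.

**Wagstaff decomposition.** The outcome model y = α + Σₖ βₖxₖ + ε is fitted
by weighted least squares (statsmodels WLS behind `weighted_ols`, with a
pivoted-QR rank pre-check so a collinear design raises a named error).
Then

    C = Σₖ ηₖ Cₖ + GC_ε/μ,    ηₖ = βₖ x̄ₖ/μ,
    GC_ε = 2 Σᵢ wᵢ εᵢ (Rᵢ − ½),

with Cₖ the contributor's own concentration index over the same ranks and
x̄ₖ its weighted mean. Because WLS residuals are weight-orthogonal to the
design and the weighted mean rank is exactly ½, the identity is algebraic:
the additivity gap is ~1e-15 on every input and is asserted below 1e-10 at
run time. Parental education enters as high-school and university
indicators with none/primary as reference. A constant contributor has
Cₖ = 0 by convention; a (numerically) zero-mean contributor has no relative
index and raises an error. Shares ηₖCₖ/C are signed; the residual share is
GC_ε/(μC).

**Oaxaca-type change decomposition.** For rounds t−1, t:

    ΔC = Σₖ [ηₖₜ(Cₖₜ − Cₖ,ₜ₋₁) + Cₖ,ₜ₋₁(ηₖₜ − ηₖ,ₜ₋₁)] + Δ(GC_ε/μ).

The default weighting (current-period elasticity on ΔC, base-period index
on Δη) is one of two standard variants; the mirrored and symmetric-average
variants are selectable and all satisfy the additivity identity exactly.
Percent-of-change is each contributor's total over the overall change
(residual included), so the percent column sums to 100 even when the change
is negative. Report tables round to two decimals and integer percents, but
percents are always computed from unrounded terms — the printed rows of a
published table generally do not re-add exactly at printed precision.

**Gibbs-sampled uncertainty for shares.** Conjugate normal–inverse-gamma
regression on the weighted likelihood (weights scaled to mean 1 so the
effective sample size is n): β | σ² is multivariate normal, σ² | β inverse
gamma. Defaults: isotropic Normal(0, 10⁶·I) prior on coefficients
(precision 10⁻⁶), InvGamma(10⁻³, 10⁻³) on σ², 5000 retained draws after
1000 burn-in, all configurable and fully determined by (data, config,
seed). Per draw the elasticities and shares are recomputed with Cₖ, x̄ₖ, μ
and the total index held at their sample values; the equal-tail 95%
interval is the (2.5, 97.5) percentile pair (linear-interpolation order
statistics). Holding ranks and contributor indices fixed understates their
sampling uncertainty; this is a deliberate, documented simplification —
only coefficient and error-variance uncertainty is propagated.

**Multiple imputation.** Chained equations with a transparent sampler: per
incomplete column, a linear model on all other analysis variables fitted to
the originally observed rows; missing cells are redrawn as prediction +
Normal(0, σ̂) for continuous columns, a latent draw thresholded at 0.5 for
binaries, and a latent draw rounded onto {0, 1, 2} for the education
categories. Initial fills are draws from each column's observed empirical
distribution; observed cells are never altered; imputation runs within
survey round; the sampling weight is not a predictor and is never imputed.
Defaults are m = 20 completed datasets and 50 regression-switching cycles.
The index and its SE are computed per completed dataset and pooled by
Rubin's rules (total variance W̄ + (1 + 1/m)B; t interval with
Barnard–Rubin degrees of freedom when the complete-data size is supplied,
falling back to the normal interval when m = 1 or B = 0). Multiple
imputation feeds only the RCI; the decomposition stages are complete-case
by design, with dropped-row counts logged. Parity with any particular
survey package's MICE implementation (predictive mean matching, per-column
model customization) is out of scope. An exclusion rule (e.g. children
without a resident parent) is supported as a boolean-column flag applied
before imputation.

## Score standardization

Per (round, integer age) cell, the mean and SD are recovered from the
cell's minimum a, median m, maximum b and size n. The standalone
`hozo_mean`/`hozo_sd` functions default to the published n-regime
recommendations — mean (a+2m+b)/4 for n ≤ 25 and m above; SD by the exact
small-sample formula for n ≤ 15, (b−a)/4 for 15 < n ≤ 70, (b−a)/6 beyond —
with all thresholds exposed as arguments.

The `AgeZScorer` transformer, however, defaults to applying the basic
formulas at every cell size: mean (a+2m+b)/4 and SD (b−a)/4 (keeping the
exact formula below n = 15). The reason is substantive: with the large-n
branches the estimated mean is the median, so any near-symmetric or
left-skewed cell yields z-scores with mean ≈ 0 or below — and the
*relative* concentration index, which divides by that mean, becomes
degenerate or sign-flipped. Under left skew the formula mean sits below the
median, giving the z-scores the positive mean (≈ 0.1–0.3 here) that makes
the mean-normalized index well defined and matches the reported behaviour
of this analysis design on real survey data. Sexes are pooled within cells;
cells are fit on all rows with observed score and age before any
exclusions; min/median/max are order statistics, so sampling weights do not
enter the summaries. A cell with zero spread raises a degenerate-cell error
naming the cell.

## Synthetic-data generator

The generator emulates a repeated cross-sectional child survey round:

- **log-PCE** ~ Normal(profile mean, profile SD); per-round profiles supply
  the marginal covariate levels (two bundled profiles reflect a
  lower-coverage year 2000 and a higher-coverage year 2007; any level can
  be overridden).
- **Binary covariates**: Bernoulli with logit(p) = logit(p₀) + g·(u − ½),
  where u is the child's fractional expenditure position and g the
  configured gradient (log-odds over the full rank span). Education is an
  ordered-logit three-level category; parental CES-D depression scores are
  gamma draws with mean multiplied by exp(g·(u − ½)). Positive g therefore
  means concentrated among the better-off, giving known-sign ground truth
  for every contributor index.
- **Raw score**: a latent linear index (intercept 5.2 + 0.40·(age − 7) +
  Σₖ βₖxₖ + Normal(0, 1.5)) rounded and clipped into 0–12. Defaults place
  the distribution above the scale midpoint with a mild ceiling — mildly
  left-skewed and increasing in age — while keeping ceiling clipping rare
  (≈ 1–2%) so linear-regression coefficient recovery is essentially
  unbiased. The skewness knobs are free parameters, not calibrated targets.
- **Weights**: gamma with mean 1 and configurable dispersion; dispersion 0
  degenerates to the unweighted case.
- **Missingness**: MAR, with row propensity logit-linear in standardized
  log-PCE (slope −0.8) and age (slope −0.3) — poorer, younger children have
  more missing parental/household data — and an intercept calibrated by
  root-finding so the realized marginal rate matches the configured one.
  The outcome, age, log-PCE, weight and round label are never masked, so
  the ranking variable is always observed.

What the generator does **not** emulate: multi-stage cluster sampling and
design effects beyond individual weights, household structure (siblings
share nothing), attrition between rounds, item-level psychometrics of the
score, and measurement error in expenditure. Passing tests on these data
therefore validate the estimators' algebra, calibration and Monte-Carlo
behaviour under the assumed structure — not robustness to clustering or
informative missingness.

A consequence of the MAR design worth noting: since the outcome, ranking
variable and weight are never missing, the per-imputation RCIs coincide and
Rubin's between-imputation variance is 0 on the synthetic path; the
complete-case vs imputation contrast is still informative because
complete-case analysis drops disproportionately poor rows and understates
the index.

## Numerical choices and problem sizes

- Additivity identities asserted at 1e-10 (observed ~1e-15).
- Undefined relative index: |mean| below 1e-12 relative to the variable's
  scale raises; |μ| < 1e-6 warns.
- Test-suite and acceptance-script problem sizes: coverage 1000 replicates
  at n = 500; additivity 200 tables at n = 200; coefficient recovery at
  n = 20 000 with 2000 retained Gibbs draws; the imputation check uses
  n = 4000, m = 20, 10 cycles — sizes chosen so each check is decisive at
  its tolerance while the full suite runs in minutes.
- Determinism: every stochastic component takes a seed; identical
  (config, seed) reproduce byte-identical tables, draws and pipeline JSON.

## Known limitations

- The Delta-method SE treats ranks as fixed; the Gibbs intervals hold Cₖ,
  x̄ₖ and μ at sample values. Both understate total uncertainty.
- The decomposition is descriptive, not causal; shares depend on the chosen
  contributor set and on the living-standards variable.
- The relative index is unstable when the outcome mean is near zero — an
  intrinsic property of mean-normalized indices, handled here by the
  standardization convention and diagnostics rather than by rescaling.
- The chained imputer uses linear/latent-threshold models only; it is not a
  general-purpose MICE replacement.
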