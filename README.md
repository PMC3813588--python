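# cogineq

Measurement and decomposition of socioeconomic inequality in children's
cognitive function, for epidemiologists and health economists working with
household-survey data.

## What it computes

Given child-level survey rows (a 12-item cognitive raw score, child,
parental and household covariates, log per-capita expenditure as the
living-standards variable, and person sampling weights), the package:

1. **Standardizes the score by age.** Because the raw score is skewed, each
   (survey round, age) cell's mean and SD are recovered from the cell's
   minimum, median, maximum and size with the Hozo estimator, and
   z = (raw − est\_mean)/est\_sd.
2. **Measures inequality** with the relative concentration index

   C = (2/μ) Σᵢ wᵢ yᵢ (Rᵢ − ½),

   where μ is the weighted mean of the z-score y, Rᵢ the weighted
   fractional rank in the expenditure distribution and w the normalized
   weights. C is twice the area between the concentration curve and the
   line of equality; C > 0 means better cognitive function is concentrated
   among the better-off. Standard errors come from the Delta method
   (Kakwani–Wagstaff–van Doorslaer estimator, weighted, with a Kish
   effective-sample-size prefactor).
3. **Decomposes the index.** With a weighted linear outcome model
   yᵢ = α + Σₖ βₖ xᵢₖ + εᵢ, the index splits exactly as
   C = Σₖ ηₖ Cₖ + GC_ε/μ with elasticities ηₖ = βₖ x̄ₖ/μ, contributor
   concentration indices Cₖ and the residual's generalized concentration
   index GC_ε. Contribution shares ηₖCₖ/C are signed and sum to 1 with the
   residual.
4. **Decomposes the change between two rounds** (Oaxaca-type):
   ΔC = Σₖ [ηₖₜ ΔCₖ + Cₖ,ₜ₋₁ Δηₖ] + Δ(GC_ε/μ), splitting each contributor's
   effect into changing inequality in the contributor vs changing
   elasticity (mirrored and symmetric weightings available).
5. **Quantifies uncertainty**: a conjugate normal–inverse-gamma Gibbs
   sampler on the weighted regression propagates coefficient uncertainty
   into equal-tail 95% credible intervals for contribution shares; under
   item missingness, chained-equations multiple imputation with Rubin's
   rules pools the index across completed datasets.

A seeded synthetic household-survey generator (`cogineq.generate`)
reproduces the statistical structure this analysis assumes — expenditure-
graded covariates, an age-increasing left-skewed score, positive sampling
weights, expenditure-dependent missingness — so every stage is testable
with known ground truth.

## Worked example

```python
from cogineq import (AgeZScorer, ConcentrationIndex, GeneratorConfig,
                     WagstaffDecomposition, generate_survey, build_design)

t = generate_survey(GeneratorConfig(n_children=4000, seed=42))
tz = AgeZScorer().fit(t).transform(t)           # adds the z column
est = ConcentrationIndex().fit(
    tz["z"].to_numpy(), tz["log_pce"].to_numpy(), tz["weight"].to_numpy())
print(f"RCI = {est.estimate_:.3f} (SE {est.se_:.3f}, "
      f"95% CI {est.ci_low_:.3f} to {est.ci_high_:.3f})")

X = build_design(tz)
dec = WagstaffDecomposition().fit(
    X, tz["z"].to_numpy(), tz["log_pce"].to_numpy(), tz["weight"].to_numpy())
print(dec.result_.table[["beta", "elasticity", "ck", "share"]]
      .sort_values("share", ascending=False).head(5).round(3))
```

prints

```
RCI = 0.929 (SE 0.122, 95% CI 0.690 to 1.167)
                      beta  elasticity     ck  share
log_pce              0.083       8.373  0.033  0.300
improved_sanitation  0.189       0.690  0.210  0.156
mother_edu_hs        0.199       0.471  0.271  0.137
electricity          0.297       2.221  0.035  0.083
rural               -0.109      -0.524 -0.143  0.081
```

The positive index says higher z-scores are concentrated among children in
higher-expenditure households. Expenditure itself carries the largest share
of the inequality (30%), followed by improved sanitation (16%) and maternal
high-school attendance (14%) — the contributors given the strongest
expenditure gradients and outcome coefficients in this synthetic round. The
share column sums to 1 together with the residual share (here 0.013), an
exact algebraic identity of the decomposition.

The same analysis is scriptable end to end:

```bash
cogineq generate --config gen.json --out survey.csv
cogineq zscore --data survey.csv --out survey_z.csv
cogineq rci --data survey_z.csv --out rci.json --curve-out curve.csv
cogineq decompose --data survey_z.csv --out-csv table3.csv --out-json dec.json --mcmc
cogineq change --before dec_2000.json --after dec_2007.json \
    --out-csv table4.csv --out-json change.json
cogineq run --config pipeline.json        # full two-round pipeline
```

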