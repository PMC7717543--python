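# migratescale

Multi-scale habitat-selection modelling of seasonal migration from GPS
telemetry, with a fully synthetic test bed.

Partially migratory ungulate populations (the motivating system is pronghorn
on northern prairie steppe) make habitat decisions during migration at two
nested spatial scales: where the broad **migratory neighborhood** sits within
the landscape (Johnson's second order), and which local sites the animal
steps through along the pathway itself (third order). `migratescale`
implements the full analysis chain that turns raw relocations into a single
scale-integrated map of migration habitat, for movement ecologists who want
a tested, reproducible version of this workflow — and a synthetic landscape
generator with known selection coefficients so every stage can be validated
against ground truth without any field data.

## The models

**Migration classification.** Net squared displacement (NSD) — the squared
straight-line distance from a track's first fix to each later fix — is fitted
with four nonlinear families (constant *resident*; single-sigmoid
*disperser*; double-sigmoid *migrant*,
δ/(1+e^{(θ₁−t)/φ₁}) − δ/(1+e^{(θ₂−t)/φ₂}); *mixed-migrant* with a free
return asymptote δ₂) and classified by minimum AIC. Seasonal migration
windows are θ ± 2φ. Pathways keep one location per stopover cluster and
need ≥ 20 observations.

**Third order (steps).** Each used location is matched to 5 available
locations generated from the individual's empirical step-length and
turn-angle distributions (each carrying design weight 0.2, so availability
mass equals used mass per stratum). Selection is estimated by conditional
logistic regression: maximise Σₛ [x′ᵤβ − log Σⱼ wⱼ e^{x′ⱼβ}] by Newton
iteration.

**Second order (neighborhoods).** Every individual's third-order available
points, pooled, become samples of neighborhood *use* and are contrasted 1:1
against uniform random study-area points in a logistic GLMM with an
individual random intercept, logit P(used) = β₀ + bᵢ + x′β,
bᵢ ~ N(0, σ²), fitted by adaptive Gauss–Hermite quadrature (agrees with
`lme4::glmer(nAGQ = 20)` to four decimals on shared data).

**Reduction, maps, validation.** Variables are screened univariately
(P < 0.20), pruned for collinearity (|r| ≥ 0.7), and reduced by backward
stepwise elimination (P > 0.05, quadratics before their linear partners,
the land-cover block by joint likelihood ratio). Prediction surfaces
compute exp(x′β) per pixel with covariates clamped to the sampled range and
time-dependent layers fixed to seasonal windows, then min–max stretched to
[0, 1]. The **scale-integrated step selection function (ISSF)** map is the
pixelwise product of the stretched second- and third-order maps, restretched
— a pixel at 0.80 (second order) and 0.50 (third order) combines to 0.40
before the final restretch. Validation withholds 20% of individuals per
fold (k = 5), refits the final terms, bins predictions into 10
equal-frequency habitat classes and reports Spearman's ρ between bin rank
and area-adjusted use frequency.

## Worked example

The end-to-end pipeline on the default synthetic conditions (20 × 20 km
landscape at 100 m resolution, 30 collared individuals at 4-h fixes, true
selection for grassland +1.0 and against unpaved-road density −0.5):

```python
from migratescale.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=11, out_dir="run"))
print(manifest["stages"]["classify"])
```

```
{'n_animal_years': 30, 'n_migratory': 19, 'n_resident': 11,
 'n_disperser': 0, 'percent_migratory': 63.3}
```

`run/validation_table.csv` then holds the k-fold Spearman results:

```
 scale season   rho     p  k
second spring 0.988 0.000  5
 third spring 0.794 0.006  5
  issf spring 0.939 0.000  5
second   fall 0.976 0.000  5
 third   fall 0.030 0.934  5
  issf   fall 0.515 0.128  5
```

Broad-scale ranking is recovered almost perfectly (ρ ≈ 0.99), step-scale
discrimination is weaker and season-dependent, and the integrated ISSF map
sits between the two — the expected signature when broad-scale structure
dominates the generator. The spring third-order coefficient table
(`run/coefficients_spring.csv`) recovers the generating signs: grassland
+0.27 (relative to the annual-cropland reference), unpaved-road density
−0.51 with a positive quadratic, and a −21 ± 9425 indicator for the
near-unvisited wetland class — the same near-separation signature rare
classes produce in real telemetry tables.

A CLI mirrors the stages: `migratescale all --config config.yaml --out run`
(also `simulate`, `classify`).

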