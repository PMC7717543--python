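# Methods

This note records the models, parameter choices and numerical conventions
behind `migratescale`, and what the synthetic test bed does and does not
establish about real telemetry analyses.

## Migration classification

Net squared displacement (NSD) is computed from the first fix of a track;
the daily series takes the fix nearest local noon each day. Four nonlinear
mean structures are fitted by bounded least squares (`scipy`'s trust-region
reflective, three starts per family) on the series rescaled by its maximum:

| family | mean structure | free parameters |
|---|---|---|
| resident | c | 1 |
| disperser | δ/(1+e^{(θ₁−t)/φ₁}) | 3 |
| migrant | δ/(1+e^{(θ₁−t)/φ₁}) − δ/(1+e^{(θ₂−t)/φ₂}) | 5 |
| mixed-migrant | δ/(1+e^{(θ₁−t)/φ₁}) − δ₂/(1+e^{(θ₂−t)/φ₂}) | 6 |

AIC (Gaussian, +1 for the variance) picks the family; ties go to the
simpler model. Two identifiability constraints prevent the flexible
families from absorbing noise: transition midpoints θ must lie inside the
observed window (a "migration" the data never saw is a resident profile in
disguise), and the fitted amplitude δ must exceed 3× the fit's residual SD
(genuine transitions in these data have δ/residual-SD near 100; without the
constraint, χ² logic lets a 2-extra-parameter sigmoid beat the constant
model on pure noise roughly 14% of the time). A `status_override` hook
allows manual reclassification. Mixed-migratory is treated as migratory
downstream; residents and dispersers are excluded.

Migration windows are θ ± 2φ (covering ~88% of the logistic transition);
the multiplier is this package's convention and is configurable. Within a
window, runs of ≥ 4 consecutive steps shorter than the 25th percentile of
segment step lengths collapse to their first location (a stopover is
temporary sedentary clustering, not pathway movement); both thresholds are
configurable. Segments retaining < 20 locations are excluded with a
recorded reason. Two years of one individual-season can be pooled with
`pool_segments`.

## Sampling design

Third order: for each used step, 5 available endpoints are generated from
the previous used location using independently resampled observed step
lengths and turn angles (turns are applied to the previous step's heading).
Endpoints outside the study area are redrawn up to 100 times, then placed
uniformly in the disc of radius equal to the drawn length. Available
points carry design weight 0.2 (5 × 0.2 = used mass 1) and inherit the
used location's timestamp so time-matched covariates contrast fairly.

The migratory neighborhood is the union of discs around every pathway
location with radius equal to the individual's 95th-percentile step length
("one step length", robust to outlier steps; `max` and `mean` rules are
available). The second-order design relabels all third-order available
points as neighborhood *use* (point ids retained, making the nesting
verifiable) against an equal count of uniform study-area points whose
timestamps sample the season's central window.

**Random-effect grouping.** Assigning all shared study-area available
points to a single pseudo-group makes the outcome perfectly separable by
the grouping factor (every individual's group would be all-used), leaving
the intercept variance unidentifiable. The default therefore deals the
available points out among the individuals in proportion to their used
counts, so every group carries both outcomes; the pooled pseudo-group
variant remains available via `grouping="pooled"`.

## Covariates

Land cover enters as 9 indicators with annual cropland the omitted
reference. Continuous covariates: time-matched NDVI (16-day tiles) and
snow (8-day tiles; half-open intervals, so a timestamp on a boundary
belongs to the later tile), slope with quadratic, aspect encoded as
degrees-from-south in [0, 180] (a negative coefficient therefore means
selection for southern aspects), VRM (3 × 3 resultant-vector ruggedness),
stream/paved-road/unpaved-road (with quadratic)/well densities, and the
distance to the nearest well spudded within ±16 days of the location's
timestamp. With no active well that distance is capped at the study-area
diagonal — the same neutral state assumed when predicting maps.

Density rasters use a 1000 m circular moving window (the window radius is
unspecified in the source analyses; the choice is recorded in all outputs
and configurable). The exact vector operator `window_density` (clipped
length or point count over window area) is cross-checked against
brute-force fine-grid integration; the landscape rasters are its
FFT-convolution equivalent with edge-truncated window areas.

Standardisation is per order and season with population SD (divisor n;
sample SD by configuration), stored alongside the model and re-applied at
prediction time. Quadratic columns are exact squares of the standardised
linear columns, so the linear/quadratic hierarchy survives model building.
Constant columns are dropped with a warning.

## Estimators

**Third order** is conditional (fixed-effect) logistic regression for the
matched design, maximised by Newton iteration with analytic gradient and
Hessian (softmax-weighted within-stratum moments); SEs come from the
inverse observed information, and covariates without within-stratum
contrast are dropped with a warning. The default maximises the exact
matched-design likelihood (all within-stratum likelihood weights 1):
conditioning on the stratum already removes the sample-size imbalance the
0.2 weights exist to fix, and on simulated choice strata the exact form
recovers the generating coefficients without bias while the
weighted-denominator variant attenuates them by ~28%. That variant
(`weights_in_likelihood=True`) is retained and is verified against
brute-force grid search of its likelihood. With unit weights and one
available point per stratum the estimator reduces to matched-pair
conditional logistic regression (checked against the closed-form
discordant-pair estimator and against `statsmodels.ConditionalLogit`).

**Second order** is a logistic GLMM with an individual random intercept.
The marginal likelihood integrates each group's intercept by adaptive
Gauss–Hermite quadrature: an inner Newton finds each group's posterior
mode and curvature, nodes are recentred and rescaled there, and 20 nodes
then integrate even large, sharply peaked clusters accurately (plain
Gauss–Hermite is badly biased for clusters of hundreds of observations).
L-BFGS-B maximises over (β₀, β, log σ) with an analytic gradient (modes
held fixed; the induced error is of quadrature order), warm-started from
the pooled logistic fit; SEs use a finite-difference Hessian of the
gradient. On shared data the fit matches `lme4::glmer(nAGQ = 20)`
coefficients, σ and log-likelihood to ~4 decimals. At σ = 0 it matches
pooled logistic regression.

**Reduction protocol.** Univariate screening is by likelihood ratio
against the null, retaining P < 0.20; the land-cover block is tested
jointly (9 df) and a quadratic jointly with its linear partner (2 df). At
second order the screening likelihood is the pooled logistic (the GLMM is
reserved for the fits that matter); at third order it is the conditional
likelihood itself. Collinearity pruning (|r| ≥ 0.7, Pearson over
estimation rows) drops the member of each pair with weaker univariate
support, iterating to closure; quadratics follow their linear partner and
the indicator block is kept intact. Backward stepwise removal drops the
single worst term with Wald P > 0.05 per iteration; the land-cover block
is removable only on its joint LR test (its level-wise Ps are reported but
not acted on, so non-significant levels of a retained block stay in the
model), and a linear term is locked while its quadratic is present.

## Maps and validation

Relative selection is exp(x′β) without intercept or random effect (an
inverse-logit variant is available and rank-equivalent). Before
standardising, each raw covariate is clamped into the [min, max] actually
sampled by the estimation rows, so extrapolation beyond sampled conditions
is impossible by construction. Time-dependent tiles are fixed to seasonal
central windows (spring days 81–96, i.e. late March; fall days 305–320,
early November) and drilling distance to its no-active cap. Maps are
min–max stretched to [0, 1]; a constant surface stretches to all zeros
with a degeneracy flag rather than crashing. The ISSF map multiplies the
two *stretched* maps and restretches: the stated worked example
(0.80 × 0.50 → 0.40) fixes stretched inputs as the intended convention.

Validation partitions individuals (never points) into 5 folds,
re-estimates the final model's coefficients on training individuals (the
term set is not re-selected), and scores withheld used locations against
10 equal-frequency bins of the prediction distribution over the evaluation
domain — study-area pixels for second order and ISSF, stratum available
points for third order. Observed bin frequencies are divided by bin share
of the domain and renormalised (a Boyce-style area adjustment; equal-width
binning would confound bin area with selection), then correlated with bin
rank by Spearman's ρ; the pooled ρ uses fold-averaged adjusted
frequencies. A single pooled ρ over 10 bins has a null SD near 1/3 —
null-calibration checks should average over replicate data sets.

## Synthetic test bed

The generator emulates a prairie-steppe landscape: quantile-thresholded
smoothed Gaussian fields for 10 land-cover classes (grassland-dominated
defaults), smoothed-noise terrain with derived slope/aspect/VRM, random
polyline road and stream networks, a Poisson well field with uniform spud
dates, 23 16-day NDVI tiles with a south-to-north green-up lag peaking
mid-summer, and 46 8-day binary snow tiles with north-biased fall onset.
Defaults: 100 m resolution, 20 × 20 km, ~0.15 wells/km² — a desk-scale
stand-in that preserves the structure (several habitat patches per home
range, networks crossing the extent, latitudinal phenology) without the
source system's 30 m, 315 876 km² footprint.

Movement is habitat-biased step selection: gamma step lengths
(shape 2, scale 150 m per 4-h fix), von Mises turns (κ = 0.8), and a
choice among K = 50 candidate steps with probability ∝
exp(β_true·z + bias·cos(heading error)), where z uses landscape-wide
standardisation (stored with the truth so fits can standardise
identically). Residents home on one range centre; migrants switch to a
directed phase (bias 1.5) toward the other seasonal centre around days 81
and 305 (SD 4 d), 10 km apart by default; mixed-migrants return to a
displaced wintering site. Optional stopovers insert runs of short steps.

Two design-level simulators support estimator calibration directly:
`simulate_choice_strata` (the exact SSF choice model; 500-strata CI
coverage of the conditional logit) and `simulate_binary_panel` (grouped
logistic data; 30 × 200 GLMM coverage). Recovery through the full track
simulator is checked directionally (grassland use exceeds availability)
rather than numerically, because availability resampled from *used*
empirical distributions — the analysis design — has an estimand that only
approximates β_true.

**What passing tests do not show.** The generator's fields are smooth and
stationary; real landscapes have anisotropic terrain, correlated layers
and classification error. Fix success is perfect, there is no GPS error,
and phenology is noiseless. Directed migration itself induces structure:
used steps are straighter and more northward than turn-resampled
availability, so even with β_true = 0 both selection scales show
non-zero validation ρ — a caution that applies equally to real analyses.
Structure-free null calibration requires undirected movement.

## Problem sizes and runtime conventions

Default desk-scale analyses use a 200 × 200 grid and 30 individuals at
4-h fixes; estimator-calibration runs use 100 replicates at 500 strata
(third order) and 30 groups × 200 observations (second order). These
sizes give coefficient SEs near 0.1 — small enough to detect the
generator's effects, large enough to run on a laptop in minutes.

## Known limitations

* One simulated year: multi-year pooling is supported in the API but the
  generator does not simulate inter-annual variation.
* The NSD classifier assumes one migration per season; double or aborted
  migrations fall into whichever family fits best.
* The second-order GLMM assumes a shared β across individuals (no random
  slopes), matching the analysis it implements.
* `window_density`'s vector path is exact but O(features) per point; the
  raster path is the practical route for maps.
* Fall third-order discrimination on defaults is weak (validation ρ near
  0) — short fall windows yield few strata per individual; this mirrors
  the scale-dependence the method is designed to expose rather than a
  defect of the implementation.
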