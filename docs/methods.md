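# Methods

This note documents the models, the numerical choices, the synthetic-data
generator, and the known limitations of `windkite`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The facing statistic

The response is the binary indicator that a bird's flight heading deviates
by **strictly less than 60°** (circular difference) from the great-circle
bearing to the nearest turbine. Under directional indifference the facing
probability is 120/360 = 1/3, which anchors every null expectation in the
package. The 60° boundary itself is excluded (deviation = 60° → not
facing). All angles are degrees at every interface; radians appear only
inside trigonometric kernels.

Geometry is spherical: haversine distances and initial bearings on a sphere
of radius 6 371 000 m. At the ≤ 1.5 km ranges that matter here the
spherical-vs-planar discrepancy is orders of magnitude below GPS noise, so
no map projection is needed. Bearings are taken to the turbine base; at
> 100 m horizontal range the base/hub distinction is negligible.

Heights are treated as above-ground (AGL). Converting ellipsoidal GPS
altitude to AGL is the data supplier's responsibility; the synthetic
generator emits AGL directly. Negative heights (GPS error) are classified
LOW and counted in the data-quality report rather than dropped. The
maximum turbine height is hub height + rotor radius, or 1.5 × rotor
diameter when hub height is unknown (hub height and rotor diameter are
similar in length for the turbines of the study region). Height classes
are inclusive downward: LOW ≤ H < MEDIUM ≤ 2H < HIGH.

## Covariates

* **Wind.** Station records every 10 min in the meteorological FROM
  convention; projections convert to the blowing-TO direction by adding
  180°. Each fix is matched to the nearest record in time (ties to the
  earlier record); matches staler than 60 min flag the covariate missing.
  The wind component toward the turbine is the scalar projection of the
  wind vector onto the bird→turbine bearing, in m/s, positive when the wind
  pushes the bird toward the turbine.
* **Orographic uplift** w = v · sin(slope) · max(0, cos(aspect − wind_from)),
  where aspect is the downslope-facing compass direction; zero on flat
  ground and on the lee side; never exceeds the wind speed. Terrain
  derivatives use Horn's eight-neighbour stencil (border cells invalid).
* **Thermal uplift** uses the convective velocity scale
  w* = (g · z_i · max(0, T_s − T_ref) / T_ref)^(1/3) with boundary-layer
  height z_i = 1000 m (configurable) and T_ref the domain-mean surface
  temperature. It is static per 500 × 500 m cell: midday summer convection
  varies little in time at a fixed site compared to across sites.
* Both uplift covariates are evaluated at the **nearest turbine's** grid
  cell, not at the bird's position: they describe the flight conditions at
  the obstacle. Rotor-wake turbulence is deliberately not modelled.

## Filtering

Non-flying fixes (ground speed < 1 m/s, strict) are dropped. 1 Hz GPS
bursts are thinned by a greedy per-bird chain that keeps only fixes ≥ 5 s
after the previously kept fix; 5 s cleanly separates 1 Hz bursts from 10 s
and slower regimes without assuming any particular logger schedule. The
modelling subsets are inclusive: ≤ 1500 m for the large-scale model;
≤ 750 m *and* LOW *and* complete covariates for the near-turbine model
(records missing any model covariate are excluded listwise and counted).
Every filter stage emits a report whose drop counters must sum with the
retained count to the input count; this conservation is asserted
throughout the tests.

## The GAMM

Design: intercept + height-class levels + one centered cubic B-spline
smooth of distance per class (basis dimension 10, second-order difference
penalty, sum-to-zero constraint per class) + one dummy column per bird with
a ridge penalty (the mixed-model representation of a random intercept,
σ_b² = 1/λ_b). The inner problem is penalized IRLS with step-halving; the
outer problem selects the four log-smoothing parameters by
**Laplace-approximate marginal likelihood**, integrating out the penalized
directions (spline wiggles and bird intercepts) and maximizing over the
unpenalized ones (intercept, class levels, the linear part of each
smooth). We chose marginal ML over the REML-flavoured variant with the full
determinant because it is the criterion the standard binomial mixed-model
stack effectively optimizes and it shrinks truly-null smooths to their
linear limit more decisively; the choice is fixed. Optimization is
Nelder–Mead on log λ ∈ [−12, 18] with warm-started inner solves.

After centering, the second-order penalty leaves exactly one unpenalized
direction per smooth, so effective degrees of freedom (EDF, the block trace
of (XᵀWX + S_λ)⁻¹XᵀWX) reach 1 for a fully shrunk smooth — EDF ≈ 1 reads
"collapsed to a straight line". Smooth p-values are Wald-type χ² tests on
the penalized coefficients with the covariance truncated to rank round(EDF)
and EDF reference degrees of freedom; like all tests of penalized terms
they are approximate. Confidence bands are Wald (±1.96 SE) on the link
scale, transformed to probabilities. Partial-effect curves include the
intercept and class level (random effect at zero), so a null fit sits at
the facing base rate ≈ 1/3; extrapolation beyond the fitted distance range
is rejected.

A caveat documented from our own calibration runs (and reproduced
replicate-by-replicate by the independent mgcv implementation on identical
data): under a *true* null smooth, ML/REML-type selection leaves
EDF > 1.2 in roughly 10–25% of replicates — the EDF null distribution does
not concentrate at 1. Significance of null smooths stays near the nominal
5% level; it is the EDF itself that has heavy-tailed sampling behaviour.
Tests that require *per-replicate* EDF ≈ 1 with high probability will
therefore fail at rates any standard selector produces.

## The GLMM

Random-intercept logistic regression fitted by adaptive Gauss–Hermite
quadrature (9 nodes; each group's integral is centered on its conditional
mode and scaled by the local curvature, so accuracy is retained for long
per-bird series; 1 node would be the Laplace approximation). The outer
optimization is BFGS on (β, log σ_b) with finite-difference gradients,
warm-started conditional modes, and a finite-difference Hessian for the
covariance. Estimates, standard errors and the log-likelihood agree with
the reference implementation (lme4::glmer, nAGQ = 9) to ~10⁻⁴ on test
fixtures. Single-group data degenerate to plain logistic regression with
σ_b pinned at 0 and a warning; σ̂_b below 10⁻⁴ is reported as a boundary
fit. Rank-deficient designs are rejected naming the offending term, and a
configuration containing a predictor pair with |r| > 0.7 is rejected —
thermal uplift and turbine height therefore live in two alternative
configurations that share all other terms. Predictors enter on raw scales
(m/s, m). Nakagawa–Schielzeth R² uses the theoretical method:
R²m = σ²_f / (σ²_f + σ²_b + π²/3) with σ²_f the variance of the
fixed-effect linear predictor; R²c adds σ²_b to the numerator. No
multiple-testing correction is applied anywhere.

## Cross-validation

Tenfold, observation-level random folds by default (a bird-level split is
available behind a flag). Prediction is facing = 1 when the fitted
probability exceeds 0.5; birds unseen in training contribute a random
effect of zero, seen birds use their estimated intercept. A randomization
in which a training fold lacks one response class is redrawn (max 5,
logged). Accuracy is the mean ± SD over folds of percent correct. For the
GAMM, smoothing parameters are selected once on the full data and held
fixed across fold refits (coefficients are re-estimated per fold); full
re-selection per fold is available via a flag. With a facing base rate of
1/3 and weak predictors, majority-class behaviour puts accuracy near 67%;
accuracy is therefore a coarse fit summary, not an effect measure.

## Diagnostics

Temporal: per-bird sample ACF (lags in fix index, as the standard ACF
computes them — a documented limitation when fix intervals vary), averaged
over birds with length weights; envelope ±1.96/√N. Spatial: Moran-type
correlogram — mean cross-product of standardized residuals over point pairs
binned by great-circle distance — with a pointwise 95% envelope from 199
seeded permutations of residuals over locations; bins with < 30 pairs are
flagged. Both are pure functions of (residuals, coordinates/times, seed).
Envelopes are pointwise: with k bins, ~5% of null bins fall outside by
construction, so calibration is judged by the out-of-envelope *fraction*.

## The synthetic generator

The generator emulates the study conditions: turbines in linear rows along
a synthetic ridge (spacing 500 m; layouts closer than 50 m are rejected), a
terrain grid with non-zero slope under the rows whose aspect faces the
prevailing wind, 10-min wind records (von Mises directions, Gamma speeds),
and birds whose per-step facing logit is

    η = η₀ + b_i − δ · invlogit((d₀ − d)/s) · 1[LOW]
        + β_w · w_c · 1[LOW, d ≤ d₀]

with defaults η₀ = logit(1/3), avoidance depth δ = 1 (facing probability
≈ 0.16 under the turbines), range d₀ = 750 m, ramp width s = 150 m (the
decline happens mostly between ~1000 and ~500 m), wind slope β_w = −0.06
per m/s, and bird-intercept SD σ_b = 0.3. Given the facing draw, the
heading is uniform inside the ±60° cone toward the turbine or uniform over
its complement — the facing indicator is sufficient by construction, and no
finer angular structure (e.g. the turning-angle pile-up just outside the
cone seen in real avoidance) is imposed. Birds advance along the drawn
heading at a Gamma airspeed plus a partial wind drift, reflecting at the
domain boundary; heights are drawn per step from a LOW/MEDIUM/HIGH mixture
relative to the current nearest turbine. Every emitted point stores its
true distance, bearing, wind component, class and facing probability,
computed with the *same* primitives the annotation pipeline uses, so
generator and annotator agree to numerical precision and round-trip through
the CSV dialects exactly.

The default scenario uses 30 birds × 200 steps (≈ 5,000 modelled points)
and the near-turbine recovery scenario 100 birds × 160 steps; these sizes
were chosen so that replicated simulation studies (50–100 refits) remain
routine on a single CPU while leaving all effects comfortably detectable.

**What the generator does not emulate, and one consequence it does.** No
thermalling circles, no collision events, no displacement/barrier effects,
no logger duty cycles. One *real* property it does reproduce: because
facing draws steer the movement, a bird's random intercept becomes
correlated over time with its average position relative to turbines (birds
that face more end up closer; measured cor(b_i, mean distance) ≈ −0.4 at
σ_b = 0.3). Trajectory data therefore violate the random-effect exogeneity
assumed by mixed models — a subtle feedback that mildly biases
coefficients on covariates whose bird-level means co-vary with the
intercepts. Calibration experiments that require exact type-I error are
accordingly run with σ_b = 0, where the generative model satisfies the
estimator's assumptions exactly; passing them says the *estimator* is
sound, not that real trajectories are feedback-free.

## Numerical conventions

Linear predictors are clipped at ±30 before exponentiation; IRLS weights
floored at 10⁻¹⁰; nearest-turbine ties within 10⁻⁹ m resolve to the
lexicographically smallest id; wind-record time ties resolve to the earlier
record; seeds propagate through `numpy.random.SeedSequence` children (one
per generator stage), so identical configurations give byte-identical
outputs. CSV timestamps are ISO 8601 UTC.

## Known limitations

* Smooth-term p-values are approximate Wald tests on penalized
  coefficients; EDF sampling variability under the null is heavy-tailed
  (see above).
* The CV accuracy of a rare-ish binary response mostly reflects the base
  rate.
* The thermal-uplift formula is a convective scale with a fixed
  boundary-layer height; only its monotonicity and non-negativity are
  treated as contractual.
* Temporal ACF lags are fix-index, not wall-clock.
* The movement model is kinematically simple; it exists to exercise the
  statistics, not to study movement.
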