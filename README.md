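# windkite

Wind-turbine avoidance analysis for GPS-tracked soaring birds.

Collisions with turbine rotor blades are a major conservation concern for
soaring raptors. One way to ask whether birds *recognize and avoid* turbines
is directional: if flight directions are random with respect to the nearest
turbine, a bird's heading should deviate less than 60° from the bearing to
that turbine exactly 1/3 of the time (a 120° cone out of 360°). Avoidance
shows up as a facing probability *below* 1/3 that deepens as birds get close
— but only for birds flying low enough to collide. `windkite` implements
that analysis end to end for movement ecologists: trajectory annotation,
the facing-turbine statistic, the avoidance models, residual diagnostics,
and a synthetic-track generator with known parameters so every stage can be
validated by parameter recovery.

## The models

Each GPS fix *i* of bird *b* yields a binary response
`y_i = 1{ Δ(heading_i, bearing_i) < 60° }` where `bearing_i` points to the
nearest turbine. Two binomial (logit) mixed models are fitted:

**Large scale (≤ 1500 m).** A GAMM with a separate penalized smooth of
distance per flight-height class and a bird random intercept,

    logit P(y_i = 1) = f_{class(i)}(d_i) + u_{b(i)},   u_b ~ N(0, σ_b²)

with height classes LOW (up to the maximum turbine height H = hub height +
rotor radius, or 1.5 × rotor diameter when the hub height is unknown),
MEDIUM (H to 2H) and HIGH (above 2H). Smooths are cubic B-splines
(dimension 10, second-order difference penalty); smoothing parameters and
σ_b are selected by Laplace-approximate marginal likelihood.

**Near turbines (≤ 750 m, LOW).** A GLMM with bird age and sex, orographic
uplift, thermal uplift *or* turbine height (the two are kept in separate
configurations because they are strongly collinear), and the signed wind
component blowing toward the turbine, `w_c = v·cos(θ_to − bearing)`:

    logit P(y_i = 1) = x_iᵀβ + u_{b(i)}

fitted by maximum likelihood with adaptive Gauss–Hermite quadrature, with
Wald inference, Nakagawa–Schielzeth R², and tenfold cross-validated
accuracy.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
scenario (30 birds, 30 turbines in two ridge rows, wind-aware movement,
known avoidance parameters):

```
python analysis/01_simulate_scenario.py
python analysis/02_annotate_tracks.py
python analysis/03_fit_avoidance_models.py
```

which prints, for the default avoidance scenario (seed 1):

```
GAMM on 4984 points (<= 1500 m):
  s(distance):low     EDF 1.00  chi2  15.63  p 7.71e-05
  s(distance):medium  EDF 1.00  chi2   0.14  p 0.712
  s(distance):high    EDF 1.00  chi2   3.66  p 0.0557
  bird intercept SD 0.191; 10-fold CV accuracy 68.4 +/- 3.4 %
  P(facing | low) at 200/750/1400 m: [0.241, 0.287, 0.352]
  ...
GLMM (with_thermal) on 734 points, 30 birds; R2 marg/cond 0.061/0.079:
  ...
  wind_component_ms      -0.066 (SE 0.014, Z -4.69, p 2.75e-06)
```

Reading this: the low-height smooth is highly significant and the fitted
facing probability falls from the random-orientation value (≈ 1/3) at
1400 m to 0.24 at 200 m — the birds avoid pointing at turbines they could
hit — while the medium/high classes stay flat at 1/3. Near the turbines,
each extra m/s of wind pushing a low-flying bird toward the turbine lowers
the facing logit by 0.066 (the generator's true value is −0.06; the second
configuration, with turbine height instead of thermal uplift, returns the
same estimate). `analysis/04_residual_diagnostics.py` and
`analysis/05_parameter_recovery.py` add the autocorrelation checks and a
replicated recovery experiment (mean estimate −0.0603 over 10 replicates of
the truth −0.06).

The same pipeline is scriptable from the shell via the `windkite` console
tool (`simulate | annotate | fit-gamm | fit-glmm | cv | diagnose | report`),
whose stages pipe into each other through CSV/JSON files.

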