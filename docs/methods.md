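# Methods

## The cohort model

The population of adults in England is partitioned into four states:
normoglycaemia (NG), intermediate hyperglycaemia (IH), type 2 diabetes
(T2D) and death. Counts are real-valued millions; the agent-level
simulator is the only integer path. The chain is time-homogeneous with a
1-year cycle: one row-stochastic matrix **P** applies every year, and the
state vector evolves as **x**ₜ₊₁ = **x**ₜ**P**. Mortality and between-state
moves are drawn from the same row in a single annual update — no
half-cycle correction is applied, consistent with the 1-year cycle and the
residual rule below.

Assumptions worth making explicit:

* **Closed cohort.** No adults enter NG over the horizon (a configurable
  constant annual NG inflow exists, default 0, for sensitivity use). The
  conserved quantity ng+ih+t2d+dead is checked to 1e-9 relative over 20
  cycles in the tests.
* **Constant probabilities.** Transition probabilities do not vary with
  age or time; this mirrors the published parameter sets being projected.
* **Residual diagonals.** The probability of remaining in a live state is
  always recomputed as 1 − Σ(exits). One published source prints an
  IH→IH value (0.836) that is inconsistent with its own printed outflows
  (1 − (0.0897+0.036+0.019) = 0.8553); the engine follows the residual
  rule, and a parameter set whose outflows exceed 1 is rejected with an
  error naming the row. Row sums are asserted to 1e-12 on every build.
* **State order** is (NG, IH, T2D, DEAD) in every array and CSV.

### Parameter sets

| parameter | model 1 (HbA1c) | model 2 | model 3 (IGT) |
|---|---|---|---|
| NG→IH   | 0.0686 | 0.0686 | 0.163 |
| IH→NG   | 0.0897 | 0.0897 | 0.162 |
| NG→T2D  | 0      | 0      | 0     |
| IH→T2D  | 0.036  | 0.013  | 0.060 |
| T2D→IH  | 0      | 0      | 0.005 |
| m_NG    | 0.006  | 0.006  | 0.006 |
| m_IH    | 0.019  | 0.019  | 0.023 |
| m_T2D   | 0.023  | 0.023  | 0.022 |

Model 1's IH→T2D uses the meta-analytic 0.036 rather than the 0.0355
printed in the source's parameter table, because model 2's 0.013 is
defined as a third of 0.036. Model 2 is model 1 with IH→T2D re-fitted
(see Calibration). Mortality values are stored at the printed precision
(3 decimals); the mortality module exists to re-derive them.

### Baseline (2015)

T2D is initialised at `t2d_share × diabetes_total` with `t2d_share = 0.9`,
because all headline outputs are on the T2D scale; initialising with all
diabetes (3.81) is available via `t2d_share=1.0`. IH is 5.05 million (an
IH=0 variant probes the unreliability of IH diagnosis), and NG is the
residual of the adult population. The adult population is a required
input with **no default**; the analysis configs use 42.9 million, the ONS
mid-2015 estimate of the England population aged 18+. The non-T2D tenth
of diabetes is simply outside the modelled cohort.

## Mortality derivation

A state's annual mortality probability is m = HR × Σ_b w_b·r_b: the
state's age distribution w weights an age-specific reference mortality
schedule r, scaled by the state's hazard ratio. The combining formula is
a modelling choice of this package: it is the construction under which a
younger age profile puts NG mortality (0.6%) below the general adult rate
(0.9%) at HR = 1, and HR = 1 reproduces the reference exactly. Inputs are
treated as annual probabilities throughout; no rate↔probability
conversion is applied (the sub-2% magnitudes make the difference
negligible). The reference schedule is an explicit input — the package
does not decide whether the "without diabetes" and "normoglycaemia"
reference groups share one schedule; callers supply what they mean.

Hazard ratios: diabetes 1.32, T2D 1.28; for IH, 1.32 under IGT and 1.0
under HbA1c (the estimated 0.97, CI 0.88–1.07, is not significantly
different from 1, so it is applied as exactly 1). Other risk measures
have no policy and raise an error. Outputs are capped at 1 with a
warning. Sex-stratified schedules are out of scope.

## Trend model

Ordinary least squares of diagnosed counts (millions) on raw calendar
years — uncentred, so coefficients are directly comparable with the
published regression table, whose intercept (−219) is a rounded value;
projections always use the unrounded coefficients. The regression scale
is diagnosed *counts*, not percentages: the published per-year increase
(0.110) matches the diagnosed-count series, and the published
first/last "true prevalence" endpoints (2.36, 4.26) are exactly the
diagnosed endpoints × 4/3.

Projection intervals are **mean-response** confidence intervals,
t(df)·s·√(1/n + (x−x̄)²/Sxx), not prediction intervals: the published
2025 band (±0.12M on 4.91M) is far too narrow for a prediction interval
on a 14-point series. The ×4/3 and ×0.9 conversions are applied to
points and interval endpoints after fitting. One published quirk is
documented rather than imitated: the intercept's printed 95% bounds are
in reversed order; this package reports bounds in natural order.

## Calibration

Model 2 is reconstructed by bounded scalar minimisation of the unweighted
sum of squared differences between the projected T2D compartment and the
PHE trajectory on the T2D scale (published diabetes projections × 0.9) at
2015–2035 in 5-year steps. The loss and matched years are implementation
choices (the construction is described qualitatively in the sources);
both are configurable. The optimiser is deterministic: a 101-point grid
pre-pass brackets the minimum (the objective is smooth but near-flat in
explosive regimes), then Brent-style bounded minimisation with tolerance
1e-8 refines it. Self-recovery of a known probability is exact to 1e-6
in the tests. Under the documented baseline the fitted IH→T2D value is
≈0.0132 — matching the published 0.013 and below the lowest reviewed
progression rate (0.02).

## Comparison statistics

* diagnosed→true: ×4/3 (75% diagnosed share); diabetes→T2D: ×0.9. The
  two commute; composition is checked to 1e-12.
* mean annual increase: (last − first)/(elapsed years), from each source's
  first to last estimate; "2004–2005 to 2017–2018" spans 13 elapsed
  fiscal years. Computed from printed endpoints the published values
  reproduce to printed precision (PHE's exact 0.0565 sits on the rounding
  boundary of its printed 0.056); the diagnosed-series value computes to
  0.146 where 0.147 is printed — presumed rounding of unprinted inputs,
  documented, not forced.
* prevalence-based identity: N(t) = Σ_strata D(t)·P(t).
* The comparison table carries every source on both true scales
  (t2d_true = 0.9 × diabetes_true to 1e-9 in every row); interval bounds
  are reported on the T2D scale, alongside the headline column. Reported
  tables round to 2 decimals for millions and 3 for rates; computation is
  full precision.

## Synthetic data

The generators emulate the external inputs:

* **Diagnosed series**: intercept −218.67, slope 0.110 M/yr, i.i.d.
  Gaussian noise sd 0.03, fiscal years 2004–2017. The intercept places
  the 2004/05 count at 1.77M (= 2.36 × 0.75) and the noise level yields
  an adjusted R² ≈ 0.995, matching the near-perfect linearity of the real
  register. No autocorrelation is modelled (none is evidenced). What
  passing tests do *not* show: robustness to register-definition changes
  or non-Gaussian disturbances in the real series.
* **Age schedules**: weights ∝ exp(skew × position), rates geometric in
  band index (7 bands, base 0.0005, gradient 2.2 in the analysis). The
  per-state skews in `analysis/01_simulate_inputs.py` were solved so the
  derived mortalities reproduce the English 2015 magnitudes (NG 0.6%,
  all adults 0.9%, IH 1.9%, T2D 2.3%); they are stand-ins for survey age
  distributions and life tables, not estimates of them.
* All generators are seed-deterministic; the age-schedule generator is a
  deterministic function of its parameters (its seed argument exists for
  interface uniformity).

## Numerical choices and degenerate inputs

Row-stochasticity tolerance 1e-12; cohort conservation 1e-9 relative;
weights-sum tolerance 1e-9. Tiny negative round-off (> −1e-12) from the
matrix product is clamped to 0. Horizon = baseline gives a length-1
trajectory; an all-zero state propagates as zeros; an all-dead cohort is
constant. Agent allocation uses largest-remainder apportionment, so
compartment totals are conserved exactly in the simulator. Fits require
≥3 points and non-degenerate years. The deterministic projection is
validated against the agent simulator's expectation (100 000 agents,
5 cycles, within 3 binomial standard errors).

## Problem sizes

The analysis projects 4-state cohorts over 20 annual cycles, fits a
14-point regression, and checks interval coverage over 500 simulated
series — sizes chosen to match the study conditions being reproduced;
everything runs in seconds.

## Known limitations

* No age structure or time variation in transition probabilities; no
  entrants, so long-horizon projections understate the at-risk pool.
* The IH=0 variant bounds, but does not model, IH misdiagnosis.
* Published projections from prevalence-based models are consumed as
  printed constants; their internal regressions are not re-derived.
* The exact baseline the original Markov projections used (population
  scalar; whether T2D was seeded with 0.9 × diabetes or all diabetes) is
  under-documented upstream; results here match the published 2025 values
  to within ~0.05M under the documented choices, and the documented
  ordering of models holds exactly.
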