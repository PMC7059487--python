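# t2dproj

Projections of the future prevalence of type 2 diabetes (T2D) in England,
compared across three kinds of model:

1. **Markov chain cohort models.** Adults move annually between four states —
   normoglycaemia (NG), intermediate hyperglycaemia (IH, "pre-diabetes"),
   T2D and death — under a row-stochastic transition matrix **P**. With
   state counts **x**ₜ (millions), the cohort evolves as **x**ₜ₊₁ = **x**ₜ**P**.
   Off-diagonal probabilities come from published models (two parameter
   sets: one HbA1c-based, one IGT-based); the probability of *remaining*
   in a state is the residual 1 − Σ(exits), so each row sums to one, and
   death is absorbing. State mortality is built as
   m = HR × Σ_bands w·m_ref — a hazard ratio times age-weighted reference
   mortality.
2. **An OLS trend on diagnosed counts.** Diagnosed-diabetes register counts
   (QOF, millions) are regressed on calendar year; the fitted line is
   extrapolated with 95% mean-response intervals,
   ŷ(x) ± t·s·√(1/n + (x−x̄)²/Sxx).
3. **Published prevalence-based projections** (N(t) = Σ D(t)·P(t) over
   age–sex strata), consumed as printed constants for comparison.

Two ratios make the scales commensurable: true prevalence =
diagnosed × 4/3 (75% of cases are diagnosed), and T2D = 0.9 × diabetes.
A one-parameter calibration shows what IH→T2D progression rate the lowest
(prevalence-based) projection implicitly assumes.

The package is aimed at epidemiologists and health-policy modellers who
want a transparent, testable re-implementation of this comparison, with
every input replaceable by a file of their own.

## Worked example

```python
from t2dproj import (BaselineEstimate, baseline_state, build_matrix,
                     make_model, project)

baseline = BaselineEstimate(diabetes_total=3.81, ih_total=5.05,
                            adult_population=42.9)   # ONS mid-2015, 18+
start = baseline_state(baseline)   # NG 34.04, IH 5.05, T2D 3.429 (millions)
traj = project(start, build_matrix(make_model("model1")), 2035)
print(f"{traj.t2d(2025):.2f}")     # 5.69
```

The full analysis is a sequence of numbered drivers:

```
python analysis/01_simulate_inputs.py     # synthetic QOF series + age schedules
python analysis/02_mortality_rates.py     # state mortality from HR x age-weighted rates
python analysis/03_markov_projections.py  # models 1-3 and IH=0 variants to 2035
python analysis/04_trend_fit.py           # OLS trend + mean-response intervals
python analysis/05_calibrate_model2.py    # IH->T2D probability matching PHE
python analysis/06_compare_projections.py # the cross-model comparison table
```

`06_compare_projections.py` prints the 2025 column (millions of adults
with T2D, true prevalence):

```
    source  t2d_true  ci_lo  ci_hi
    model2      3.87    NaN    NaN
       PHE      3.95    NaN    NaN
 QOF-trend      4.88   4.83   4.93
model1-IH0      5.05    NaN    NaN
    model1      5.69    NaN    NaN
model3-IH0      8.59    NaN    NaN
    model3      9.09    NaN    NaN
```

Reading it: the PHE projection (~3.95M) is the lowest and is matched by
the Markov model only after cutting the IH→T2D progression probability
from 0.036 to ~0.013 — below any published estimate (the lowest reviewed
rate is 0.02). The diagnosed-count trend and the review-based Markov
models instead point to roughly 5 million or more by 2025, and the
IGT-parameterised model 3 is implausibly explosive (~9M). Even with the
IH compartment emptied at baseline (IH=0), both review-based models stay
above the PHE projection.

There is also a CLI (`t2dproj simulate | project-markov | fit-trend |
calibrate | compare | plot`, see `t2dproj --help`), a thin wrapper over
the same functions.

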