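# Methods

## PDC computation

Dispensing records for all DOAC agents are pooled into one supply
stream per patient (switching agents preserves carry-over). Gap
adjustment shifts each fill's effective start to the later of its
dispense day and the previous fill's effective end, so early refills
stockpile supply indefinitely and total covered days always equal total
days supplied. Day offsets are 0-based from the index date — by default
the first DOAC dispense date, configurable — and windows are half-open:
window *k* spans days `[90(k−1), 90k)`.

Hospitalized days count toward the numerator (inpatients receive
medication from the hospital). The credit is computed as a day-set
union by default — `numerator = |covered ∪ hospital| ∩ window` — so a
hospital day that overlaps drug coverage is not double counted and the
PDC cannot exceed 1 before capping; a `sum` mode (raw addition, capped
at 90) is available in the config because claims pipelines differ on
this point. Each window's PDC is `min(covered + hospital, 90)/90`.

States: percentage bins are left-closed, right-open (`[0,10), [10,20),
…`) with the top bin `[90,100]` closed. This covers every realizable
value `100·n/90` and matches the printed bin labels 0–9 %, …, 90–100 %.
Eligibility ("on therapy at least two months") is operationalized as
≥ 2 dispensing records totalling ≥ 60 days supplied, both configurable,
since claims alone cannot distinguish the other readings.

## Transition model

The outcome is the ordinal state at windows 5–20 (years 1–5; 16
outcome windows per patient). First-order Markov structure: each
window's state is conditioned on the previous window's state, time, and
baseline covariates. The likelihood is the cumulative-logit
proportional-odds model, oriented so that `P(Y ≥ j) = expit(α_j +
xᵀβ)`: a positive coefficient means better adherence.

Design choices (the original analysis leaves these open):

- **Previous state** enters as categorical indicators with the highest
  state (the modal state) as reference; a linear encoding is available
  for sparse data. Levels unseen in training are merged with the
  nearest observed level, with a warning.
- **Time** (window index) enters linearly, centered at the training
  mean; interactions multiply each spline column of a covariate with
  centered time, with main effects always retained.
- **Splines**: restricted cubic, 4 knots, Harrell's truncated-power
  basis (linear term + 2 nonlinear terms, exactly linear outside the
  boundary knots; nonlinear columns are identically zero below the
  first knot). Knots default to the 0.05/0.35/0.65/0.95 quantiles; for
  the covered-day predictors — which pile up at 90 and make quantile
  knots degenerate — the pipeline default is fixed knots at
  (30, 60, 80, 89) days, putting the outer knot at the one-missed-day-
  a-month boundary where the effect is steepest; the integer risk score
  uses fixed knots (2, 4, 5, 7). Spline bases are centered at the
  variable's centering constant so the reference row is all-zero.

**Estimation.** Newton–Raphson with step halving on the exact negative
log-likelihood, started from the always-feasible intercept-only
solution (marginal cumulative log-odds, β = 0). Intercept ordering is
maintained by a `+inf` barrier in the line search rather than a hard
reparameterization, keeping the covariance interpretable. Gradient and
Hessian are analytic (both verified against finite differences in the
suite); the observed information at the optimum supplies the
covariance. Convergence requires gradient sup-norm < `tol·(1+|ℓ|)`,
`tol = 1e-8`; non-convergence returns a flagged fit rather than raising.
No cluster-robust correction is applied: the Markov conditioning is the
modeled dependence mechanism, and on self-generated data the model is
exactly correct, which the calibration suite verifies.

Model comparison fits a fixed ladder of ten candidates (basic model =
age + score + four first-year windows; variants add time interactions
on windows 3–4, drop covariates, or drop windows) and ranks by AIC,
with likelihood-ratio tests against the basic model.

## State occupancy

For one subject, the one-step transition matrix at window *t* stacks
the predicted distributions for each possible previous state. Occupancy
starts at the **observed** window-4 state (never predicted) and is
propagated by `π_t = π_{t−1} P_t` over windows 5–20. The horizon is 16
windows by default (`horizon: 21` adds the 17th). Mean time in state
*j* is `Σ_t π_t(j)`; the per-subject totals sum to the horizon length
exactly. Collapsing to 4 states ({1}, {2–7}, {8,9}, {10}) or 3 states
({1}, {2–9}, {10}) sums member probabilities; collapse and recursion
commute, which the suite asserts.

## Diagnostics

- **Subject calibration**: each subject-window's predicted expected
  state `Σ_j j·π_t(j)` versus the observed state; subjects are ranked
  by their mean predicted state into deciles (ties broken by stable
  rank on subject id, for determinism) and group means are compared.
  Time strata: early = window 5, middle = windows 6–12, late = 13–20.
- **Smoothed calibration**: penalized B-spline scatterplot smoother
  with the penalty weight chosen by generalized cross-validation
  (statsmodels GAM); a noiseless relation falls back to unpenalized
  spline least squares.
- **Transition reliability**: one-step predicted probability of landing
  in a state of interest (default 10, 9, 1), decile-binned against the
  observed event fraction.
- **SOP distribution width**: per state and window, the IQR length of
  occupancy probabilities across subjects, using linear interpolation
  between order statistics (stated explicitly because width is a
  headline statistic); time-averaged per state, with a subject-
  resampling bootstrap (default 100 reps, seeded) reporting the median
  and 2.5/97.5 percentile envelope. Note the extreme-percentile
  envelope from 100 replicates is systematically a little narrow; the
  bootstrap median is stable from 100 reps, the envelope from a few
  hundred.
- **Mean-time error**: per subject `|Σ_t π_t(10) − #{t: observed state
  = 10}|` over windows 5–20, summarized by median and IQR. "Observed
  time in the top state" is the count of observed windows in state 10,
  the natural discrete analogue.

## Synthetic cohort generator

The generator defines the study conditions every test runs under.
Baselines: age from a truncated skew-normal (median ≈ 78, IQR ≈ 73–85),
CHA2DS2-VASc from the published cohort's frequency table (mode 4–5).
First-year coverage: half the patients have gap-free first years; the
rest draw a Gamma gap propensity, with per-window Poisson gap days and
a mild erosion factor across windows 1–4, reproducing covered-day
medians of 90 with lower quartiles drifting from the mid-80s to the
mid-70s. The first window's gap is capped so every patient meets the
two-month eligibility rule. About 10 % of patients get one 3–14-day
hospital stay in year 1.

States for windows 5–20 are drawn sequentially from a known
proportional-odds transition model (`TrueModel`). Its effects are
closed forms — adherence rising with age to a plateau at 75, a modest
positive score effect, covered-day effects with a steep logistic rise
near 87–90 days, strong negative persistence offsets for low previous
states (discontinuation is near-absorbing), a mild negative time trend,
and by default time interactions on windows 3–4 — projected by least
squares onto the centered spline basis, so the generating truth is
exactly representable by the fitted model class and the induced
coefficient vector is the target of recovery tests. Drawn states are
converted back to covered days (uniform within the state's day range,
with extra mass at 90 for the top state) and then to claim-level fills:
runs of coverage split into ≤ 30-day fills with random early refills,
rare agent switches (calibrated to ≈ 1 switcher in 8 patients over five
years), exactly reconstructible through the gap-adjustment rules.

All randomness flows from one seed through counter-based per-patient
streams, so patient *i*'s data is byte-stable under cohort-size
changes.

**What the generator does not emulate** — and hence what passing tests
do not establish about registry data: mortality and censoring,
insurer/formulary switching, per-agent adherence differences, seasonal
or calendar effects, covariate-dependent hospitalization, and
measurement error in days-supplied fields. Tests on this cohort
establish internal correctness of the pipeline (exact reconstruction,
nominal coverage, self-calibration), not external validity.

## Problem sizes and numerical notes

The suite's simulation studies use cohorts of 250–3,000 patients:
parameter recovery runs 100 replicates at n = 3,000 × 16 transitions;
model-selection consistency runs 100 seeds at n = 2,000 (pilot runs
showed AIC selection of the generating interaction structure is
underpowered at a few hundred patients, and n = 2,000 is effectively
the scale of the motivating cohort); self-calibration uses n = 2,000;
the acceptance script uses n = 1,500 with 20 recovery replicates. The
Monte-Carlo oracle for the occupancy recursion uses 200,000 simulated
chains (per-cell SE ≤ 0.0011).

Degenerate inputs are handled explicitly: empty dispensing yields empty
outputs with a warning; constant covariates are rejected at knot
selection with instructions to supply explicit knots; unordered
intercepts hit the likelihood barrier (never NaN); a singular observed
information falls back to a pseudo-inverse with a flagged fit.

## Known limitations

- Proportional odds is assumed across all nine thresholds; no
  partial-proportional-odds relaxation is provided.
- Variance estimates are model-based (observed information); no
  cluster-robust correction is provided, on the grounds that the Markov
  conditioning is the modeled dependence mechanism.
- The Wald coverage of individual spline coefficients for the integer
  risk score is nominal but those columns are highly collinear
  (condition number ≈ 100 on the integer support), so their individual
  estimates are noisy; effects should be read from the partial-effect
  curves, not single coefficients.
- Calibration is in-sample; external validation is out of scope.
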