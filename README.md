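# pdcmarkov

Long-term medication adherence trajectory modeling for pharmacy-claims
data, built around direct oral anticoagulant (DOAC) therapy in elderly
atrial-fibrillation cohorts.

Clinicians and pharmacoepidemiologists usually summarize adherence with
a single proportion-of-days-covered (PDC) number. That throws away the
trajectory: who stays nearly perfect for five years, who erodes slowly,
and who discontinues outright. `pdcmarkov` implements the full modeling
chain needed to predict those trajectories from the first year of
dispensing data:

1. **PDC engine** — gap-adjusted day-level coverage from claims
   (carry-over of early refills, pooled agents across switches,
   credited in-hospital days), aggregated into consecutive 90-day
   windows: `PDC = min(covered + hospital days, 90) / 90`, binned into
   ten ordinal states (state 1 = 0–9 %, …, state 10 = 90–100 %).
2. **First-order proportional-odds Markov transition model** — the
   state `Y_t` at each window regressed on the state at `t−1`, time,
   and baseline covariates through a cumulative-logit model

   `P(Y_t ≥ j | x) = expit(α_j + xᵀβ),  j = 2..10,`

   with one shared coefficient vector β (proportional odds) and
   restricted cubic splines (4 knots) for age, CHA2DS2-VASc score and
   the four first-year covered-day counts, optionally interacted with
   time. Fitted by Newton–Raphson on the exact likelihood; AIC and
   likelihood-ratio tests compare a ladder of candidate models.
3. **State occupancy probabilities (SOPs)** — recursive matrix
   multiplication unconditions the one-step transitions, giving each
   patient's probability of occupying every state at windows 5–20
   (years 1–5), plus mean time in state (sum of a state's SOPs, in
   90-day units) and 4-/3-state collapsed sensitivity views.
4. **Diagnostics** — decile and GAM-smoothed calibration, one-step
   transition reliability, SOP distribution width (IQR length across
   patients, the discrimination measure) with a 100-rep subject
   bootstrap, and the median absolute error of predicted vs observed
   time in the top state.
5. **Synthetic cohort generator** — claim-level cohorts with known
   transition dynamics (a `TrueModel` whose closed-form effects are
   projected onto the spline basis), so every stage is testable by
   round trip without any registry access.

## Worked example

```python
from pdcmarkov import (build_transition_table, compute_sops, fit,
                       generate_cohort, mean_time_in_state)
from pdcmarkov.synthetic import default_true_model

tm = default_true_model()
cohort = generate_cohort(n=1500, true_model=tm, seed=42, with_claims=False)
trans = build_transition_table(cohort.windows, cohort.baseline)
model = fit(tm.spec, trans)

base = dict(age=78, chads_vasc=5, days_w1=90, days_w2=90)
for label, w34 in [("90/90", 90.0), ("85/85", 85.0)]:
    sops = compute_sops(model, dict(base, days_w3=w34, days_w4=w34),
                        initial_state=10)
    print(f"windows 3-4 = {label}: mean time in state 10 = "
          f"{mean_time_in_state(sops, 10):.2f} windows; "
          f"P(state 10 at year 5) = {sops.probs[-1, 9]:.2f}")
```

prints

```
windows 3-4 = 90/90: mean time in state 10 = 13.68 windows; P(state 10 at year 5) = 0.78
windows 3-4 = 85/85: mean time in state 10 = 12.57 windows; P(state 10 at year 5) = 0.64
```

Two 78-year-old patients identical except for windows 3–4 of their
first year (90 vs 85 covered days — roughly one missed day a month):
the model expects the first to spend about 1.1 more quarters of the
next four years in the top adherence state, and the five-year
probability of still being there drops from 0.78 to 0.64. The steep
spline segment near 89 covered days is what makes this small first-year
difference matter.

The `examples/` directory has one short script per capability (PDC
windows from raw claims, cohort generation, model comparison, state
occupancy, diagnostics); each prints the numbers it computes and a line
on what they mean.

## Command line

The same pipeline is scriptable end to end from a YAML config:

```bash
pdcmarkov simulate --config run.yaml   # or point `inputs:` at your CSVs
pdcmarkov pdc      --config run.yaml   # windows.csv
pdcmarkov fit      --config run.yaml   # ladder.csv + fit.json
pdcmarkov predict  --config run.yaml   # sops.csv, mean time, figures
pdcmarkov evaluate --config run.yaml   # calibration / width / MAE report
```

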