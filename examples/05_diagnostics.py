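"""Calibration and discrimination report for a fitted model.

Computes subject-level decile calibration, SOP distribution widths with
a 100-rep bootstrap, and the median absolute error of predicted time in
the top adherence state.
"""

from pdcmarkov import (
    bootstrap_widths,
    build_transition_table,
    calibration_slope,
    compute_sops_cohort,
    fit,
    generate_cohort,
    mean_time_mae,
    sop_width,
    subject_calibration,
)
from pdcmarkov.synthetic import default_true_model

tm = default_true_model()
cohort = generate_cohort(n=1000, true_model=tm, seed=42, with_claims=False)
trans = build_transition_table(cohort.windows, cohort.baseline)
model = fit(tm.spec, trans)
sops = compute_sops_cohort(model, trans)
obs = cohort.windows[["patient_id", "window_index", "state"]]

cal = subject_calibration(sops, obs)
print(f"decile calibration slope: {calibration_slope(cal):.3f} "
      "(1.0 = perfectly calibrated)")

widths = sop_width(sops).groupby("state")["time_avg"].first()
boot = bootstrap_widths(sops, reps=100, seed=1)
print(f"SOP width state 10: {widths[10]:.3f} "
      f"(bootstrap median {boot.loc[boot.state == 10, 'boot_median'].item():.3f})")
print(f"SOP width state 1:  {widths[1]:.3f}")
print(f"SOP width states 2-9 (max): {widths.loc[2:9].max():.3f}")

med, (q25, q75) = mean_time_mae(sops, obs)
print(f"mean-time-in-state-10 MAE: median {med:.2f} "
      f"(IQR {q25:.2f}-{q75:.2f}) windows")
print(
    "\nWide occupancy distributions for the extreme states (10 and 1) "
    "against near-zero widths for intermediate states reproduce the "
    "method's discrimination profile: it separates patients well at the "
    "extremes and weakly in between."
)
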