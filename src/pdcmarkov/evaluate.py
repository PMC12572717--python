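"""Calibration and discrimination diagnostics for the transition model.

Calibration compares mean predicted ordinal state (the expected value of
the predicted state probabilities) with mean observed state across
decile groups of subjects, overall, stratified by follow-up period, and
as a GAM-smoothed curve; one-step transition probabilities are checked
with reliability tables for the states of clinical interest.
Discrimination is summarized by the SOP distribution width — the
interquartile-range length of predicted occupancy probabilities across
subjects at each window — with a subject-resampling bootstrap for
internal validation, plus the median absolute error of predicted versus
observed time in the highest adherence state.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import POFit, probs_from_design
from .sop import SOPMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "expected_state",
    "subject_calibration",
    "calibration_slope",
    "smoothed_calibration",
    "transition_calibration",
    "sop_width",
    "bootstrap_widths",
    "mean_time_mae",
    "DEFAULT_STRATA",
]

# follow-up strata over prediction windows 5..20:
# early = first window of year 2; middle = rest of year 2 through year 3;
# late = years 4-5
DEFAULT_STRATA = {"early": (5, 5), "middle": (6, 12), "late": (13, 20)}


def expected_state(probs) -> float:
    """Expected value of a state probability vector, sum_j j * p_j."""
    p = np.asarray(probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
        raise ValueError("probabilities must be non-negative and sum to 1")
    return float(np.arange(1, len(p) + 1) @ p)


def _subject_window_frame(sops: list[SOPMatrix], observed: pd.DataFrame) -> pd.DataFrame:
    """Long frame: one row per subject-window with predicted E[state] and
    the observed state."""
    obs = observed.set_index(["patient_id", "window_index"])["state"]
    rows = []
    for m in sops:
        es = m.probs @ np.arange(1, m.n_states + 1)
        for w, e in zip(m.windows, es):
            rows.append((m.patient_id, int(w), float(e),
                         int(obs.loc[(m.patient_id, int(w))])))
    return pd.DataFrame(rows, columns=["patient_id", "window_index",
                                       "predicted", "observed"])


def _decile_table(df: pd.DataFrame, n_groups: int = 10) -> pd.DataFrame:
    """Group subjects into (near-)equal deciles of mean predicted state.

    Ties are broken by stable rank on subject id, so group sizes differ
    by at most one and the grouping is deterministic.
    """
    per_subj = (df.groupby("patient_id", sort=True)[["predicted", "observed"]]
                  .mean().reset_index())
    n = len(per_subj)
    if n < n_groups:
        logger.warning("only %d subjects; using %d calibration groups", n, n)
        n_groups = max(n, 1)
    order = np.lexsort((per_subj["patient_id"].to_numpy(),
                        per_subj["predicted"].to_numpy()))
    group = np.empty(n, dtype=int)
    group[order] = (np.arange(n) * n_groups) // n + 1
    per_subj["group"] = group
    out = (per_subj.groupby("group")
           .agg(mean_predicted=("predicted", "mean"),
                mean_observed=("observed", "mean"),
                n=("predicted", "size"))
           .reset_index())
    return out


def subject_calibration(
    sops: list[SOPMatrix],
    observed: pd.DataFrame,
    strata: dict | None = None,
) -> pd.DataFrame:
    """Decile calibration of mean predicted vs mean observed state.

    ``observed`` needs columns patient_id, window_index, state.  With
    ``strata`` (name -> inclusive window range), deciles are formed
    within each stratum of follow-up time.
    """
    df = _subject_window_frame(sops, observed)
    if strata is None:
        return _decile_table(df)
    parts = []
    for name, (lo, hi) in strata.items():
        sub = df[(df["window_index"] >= lo) & (df["window_index"] <= hi)]
        t = _decile_table(sub)
        t.insert(0, "stratum", name)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def calibration_slope(table: pd.DataFrame) -> float:
    """Least-squares slope of mean observed on mean predicted."""
    x = table["mean_predicted"].to_numpy()
    y = table["mean_observed"].to_numpy()
    x = x - x.mean()
    denom = (x ** 2).sum()
    if denom == 0:
        return np.nan
    return float((x * (y - y.mean())).sum() / denom)


def smoothed_calibration(predictions, observations, grid_size: int = 100):
    """GAM-smoothed calibration curve of observed on predicted state.

    A penalized B-spline scatterplot smoother with the penalty weight
    chosen by generalized cross-validation, evaluated on a uniform grid
    over the range of predictions.  Degenerate constant predictions give
    a flat line at the observed mean.
    """
    x = np.asarray(predictions, dtype=float)
    y = np.asarray(observations, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 subject-windows to smooth")
    grid = np.linspace(x.min(), x.max(), grid_size)
    if np.ptp(x) < 1e-12:
        return grid, np.full(grid_size, y.mean())
    from statsmodels.gam.api import BSplines, GLMGam
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    # interior spread needed for a stable spline basis
    df_basis = 8 if len(np.unique(x)) >= 20 else 4
    bs = BSplines(x[:, None], df=[df_basis], degree=[3])
    basis_g = bs.transform(grid[:, None])
    try:
        gam = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs)
        try:
            alpha = gam.select_penweight()[0]
        except Exception:                   # fall back to a mild penalty
            alpha = [1.0]
        res = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs,
                     alpha=alpha).fit()
        fitted = res.params[0] + basis_g @ res.params[1:]
    except PerfectSeparationError:
        # (near-)noiseless relation: unpenalized spline least squares
        D = np.column_stack([np.ones(len(y)), bs.transform(x[:, None])])
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        fitted = coef[0] + basis_g @ coef[1:]
    return grid, fitted


def transition_calibration(
    fit_: POFit,
    transitions: pd.DataFrame,
    states_of_interest=(10, 9, 1),
    n_bins: int = 10,
) -> dict[int, pd.DataFrame]:
    """Reliability tables for one-step transition probabilities.

    For each state of interest, the predicted probability of landing in
    that state next window is binned into deciles (stable rank on row
    order) and compared with the observed event fraction.
    """
    X = fit_.builder.transform(transitions)
    P = probs_from_design(fit_.alpha, fit_.beta, X, fit_.spec.n_states)
    y = transitions["y"].to_numpy(int)
    out = {}
    for j in states_of_interest:
        p = P[:, j - 1]
        event = (y == j).astype(float)
        order = np.argsort(p, kind="stable")
        group = np.empty(len(p), dtype=int)
        group[order] = (np.arange(len(p)) * n_bins) // len(p) + 1
        t = (pd.DataFrame({"group": group, "p": p, "event": event})
             .groupby("group")
             .agg(mean_predicted=("p", "mean"),
                  observed_fraction=("event", "mean"),
                  n=("p", "size"))
             .reset_index())
        t = t[t["n"] > 0]
        out[j] = t
    return out


def _width_matrix(sops: list[SOPMatrix], idx=None) -> np.ndarray:
    """(T, K) IQR length of occupancy probs across (a subset of) subjects.

    Quantiles use linear interpolation between order statistics.
    """
    arr = np.stack([m.probs for m in sops])          # (n, T, K)
    if idx is not None:
        arr = arr[idx]
    if arr.shape[0] < 2:
        logger.warning("fewer than 2 subjects; widths are 0")
        return np.zeros(arr.shape[1:])
    q75, q25 = np.percentile(arr, [75, 25], axis=0)
    return q75 - q25


def sop_width(sops: list[SOPMatrix]) -> pd.DataFrame:
    """Per-state SOP distribution width over time plus its time average.

    Returns a frame with columns state, window_index, width, and the
    per-state time-averaged width repeated in ``time_avg``.
    """
    if len(sops) < 1:
        raise ValueError("need at least one subject")
    W = _width_matrix(sops)                          # (T, K)
    windows = sops[0].windows
    K = sops[0].n_states
    df = pd.DataFrame({
        "window_index": np.repeat(windows, K),
        "state": np.tile(np.arange(1, K + 1), len(windows)),
        "width": W.ravel(),
    })
    avg = df.groupby("state")["width"].mean().rename("time_avg")
    return df.merge(avg, on="state")


def bootstrap_widths(
    sops: list[SOPMatrix],
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap (subject resampling) envelope of time-averaged widths.

    Returns per state: the full-sample time-averaged width, and the
    median and 2.5/97.5 percentiles over ``reps`` bootstrap replicates.
    Reproducible for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = len(sops)
    K = sops[0].n_states
    rng = np.random.default_rng(seed)
    stats = np.empty((reps, K))
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        stats[r] = _width_matrix(sops, idx).mean(axis=0)
    full = _width_matrix(sops).mean(axis=0)
    lo, med, hi = np.percentile(stats, [2.5, 50, 97.5], axis=0)
    return pd.DataFrame({
        "state": np.arange(1, K + 1),
        "width": full,
        "boot_median": med,
        "boot_lo": lo,
        "boot_hi": hi,
    })


def mean_time_mae(
    sops: list[SOPMatrix],
    observed: pd.DataFrame,
    state: int = 10,
) -> tuple[float, tuple[float, float]]:
    """Median (and IQR) absolute error of predicted mean time in a state.

    Per subject: |sum_t SOP_t(state) - #observed windows in state| over
    the SOP windows, in 90-day units.  Observation windows must align
    with the SOP windows.
    """
    obs = observed.set_index(["patient_id", "window_index"])["state"]
    errs = []
    for m in sops:
        try:
            o = np.array([obs.loc[(m.patient_id, int(w))] for w in m.windows])
        except KeyError as e:
            raise ValueError(f"observed windows do not align with SOPs: {e}")
        pred = m.probs[:, state - 1].sum()
        errs.append(abs(pred - (o == state).sum()))
    errs = np.asarray(errs)
    q25, med, q75 = np.percentile(errs, [25, 50, 75])
    return float(med), (float(q25), float(q75))
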