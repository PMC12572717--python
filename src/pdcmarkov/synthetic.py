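"""Synthetic DOAC-adherence cohorts with known transition dynamics.

The generator emulates the registry structure the pipeline consumes:
an elderly atrial-fibrillation cohort (age median ~78, IQR ~73-85;
CHA2DS2-VASc mostly 3-5), high but slowly eroding first-year coverage
(median covered days 90 per 90-day window, lower quartile in the 70s-80s
by windows 3-4), claim-level dispensing records with early refills and
agent switching, occasional hospital stays, and long-term ordinal
adherence states driven by a known first-order proportional-odds Markov
model (:class:`TrueModel`).  Because the ground truth is known, every
downstream stage — PDC reconstruction, model fitting, state occupancy
recursion, calibration — can be validated by round trip.

All randomness flows from a single seed through a counter-based
per-patient stream, so each patient's data is stable under changes of
the cohort size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DesignBuilder, ModelSpec, rcs_basis
from .model import probs_from_design

__all__ = [
    "TrueModel",
    "default_true_model",
    "SyntheticCohort",
    "generate_cohort",
    "generate_dispensing",
    "simulate_trajectories",
]

N_STATES = 10
WINDOW = 90
DRUGS = ("apixaban", "rivaroxaban", "dabigatran", "edoxaban")

# covered-day ranges compatible with each ordinal state (no hospital credit)
_STATE_DAY_RANGE = {s: (9 * (s - 1), 9 * s - 1) for s in range(1, 10)}
_STATE_DAY_RANGE[10] = (81, 90)


# ---------------------------------------------------------------------------
# the known data-generating transition model
# ---------------------------------------------------------------------------

@dataclass
class TrueModel:
    """Known parameter set of the data-generating transition model.

    Covariate effects are specified as closed-form shape functions and
    projected (least squares on a reference grid) onto the restricted
    cubic spline basis, so the truth is exactly representable by the
    fitted model class and the induced coefficient vector is the target
    of parameter-recovery checks.
    """

    spec: ModelSpec
    builder: DesignBuilder
    alpha: np.ndarray                 # 9 ordered intercepts for P(Y >= j)
    beta: np.ndarray                  # aligned with builder.column_names_
    shapes: dict = field(default_factory=dict)   # closed forms, for plots

    @property
    def n_states(self) -> int:
        return self.spec.n_states

    @property
    def column_names(self) -> list[str]:
        return list(self.builder.column_names_)

    def transition_matrices(self, covariates: dict, windows) -> np.ndarray:
        """(T, K, K) stack of one-step matrices for one subject."""
        windows = np.asarray(windows)
        K = self.n_states
        T = len(windows)
        rows = pd.DataFrame({
            **{k: np.repeat(float(v), T * K) for k, v in covariates.items()},
            "time": np.repeat(windows.astype(float), K),
            "y_prev": np.tile(np.arange(1, K + 1), T),
        })
        X = self.builder.transform(rows)
        return probs_from_design(self.alpha, self.beta, X, K).reshape(T, K, K)

    def to_json(self, path, seed=None) -> None:
        d = {
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "column_names": self.column_names,
            "knots": {k: list(map(float, v)) for k, v in self.builder.knots_.items()},
            "centers": {k: float(v) for k, v in self.builder.centers_.items()},
            "n_states": self.n_states,
            "seed": seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _project_shape(f, knots, center, grid) -> np.ndarray:
    """Least-squares coefficients of a shape function on the rcs basis."""
    B = rcs_basis(grid, knots) - rcs_basis(np.array([center]), knots)
    y = f(grid) - f(np.array([center]))
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    return coef


def default_true_model(
    with_time_interaction: bool = True,
    steep_refill_cliff: float = 1.0,
) -> TrueModel:
    """The standard study conditions.

    Effect shapes follow the qualitative findings the model class is
    meant to capture: adherence rises ~linearly with age and plateaus
    around 75; a modest positive CHA2DS2-VASc effect; first-year window
    effects with a steep rise near 89-90 covered days (missing even one
    day a month separates long-term trajectories); strong previous-state
    persistence; a mild negative time trend; and, by default, time
    interactions on windows 3-4 so late-first-year adherence matters
    more as follow-up lengthens.
    """
    variables = ["age", "chads_vasc", "days_w1", "days_w2", "days_w3", "days_w4"]
    knots = {
        "age": np.array([65.0, 72.0, 78.0, 88.0]),
        "chads_vasc": np.array([2.0, 4.0, 5.0, 7.0]),
        **{f"days_w{k}": np.array([30.0, 60.0, 80.0, 89.0]) for k in range(1, 5)},
    }
    centers = {"age": 78.0, "chads_vasc": 5.0, "time": 12.5,
               **{f"days_w{k}": 85.0 for k in range(1, 5)}}
    interactions = ([("days_w3", "time"), ("days_w4", "time")]
                    if with_time_interaction else [])
    spec = ModelSpec(
        terms=[(v, "rcs4") for v in variables],
        interactions=interactions,
        knots=dict(knots),
        centers=dict(centers),
        n_states=N_STATES,
    )
    builder = DesignBuilder(spec)
    builder.knots_ = {k: v.copy() for k, v in knots.items()}
    builder.centers_ = dict(centers)
    builder.prev_levels_ = np.arange(1, N_STATES + 1)
    builder.column_names_ = builder._column_names()

    cliff = lambda d: expit((d - 87.0) / 1.5)   # steep rise at 89-90 days
    shapes = {
        "age": lambda a: 0.030 * np.minimum(a, 75.0),
        "chads_vasc": lambda s: 0.06 * s,
        "days_w1": lambda d: 0.004 * d + 0.45 * steep_refill_cliff * cliff(d),
        "days_w2": lambda d: 0.004 * d + 0.55 * steep_refill_cliff * cliff(d),
        "days_w3": lambda d: 0.005 * d + 0.70 * steep_refill_cliff * cliff(d),
        "days_w4": lambda d: 0.005 * d + 0.80 * steep_refill_cliff * cliff(d),
        # interaction shapes multiply centered time
        "days_w3:time": lambda d: 0.050 * cliff(d),
        "days_w4:time": lambda d: 0.055 * cliff(d),
    }
    grids = {
        "age": np.linspace(55, 99, 200),
        "chads_vasc": np.linspace(1, 9, 100),
        **{f"days_w{k}": np.linspace(0, 90, 181) for k in range(1, 5)},
    }
    beta_parts = [
        _project_shape(shapes[v], knots[v], centers[v], grids[v])
        for v in variables
    ]
    for v, _ in interactions:
        beta_parts.append(
            _project_shape(shapes[f"{v}:time"], knots[v], centers[v], grids[v])
        )
    # previous-state persistence (reference = state 10): strongly negative
    # for low states so discontinuation is near-absorbing
    gamma = np.array([-5.0, -4.2, -3.6, -3.0, -2.5, -2.0, -1.5, -1.0, -0.5])
    beta_parts.append(gamma)
    beta_parts.append(np.array([-0.06]))        # mild decline over time
    beta = np.concatenate(beta_parts)
    # intercepts: from state 10 at reference covariates, P(Y>=10) = 0.85
    # and only ~3% mass below state 2
    tail = np.array([0.97, 0.96, 0.955, 0.95, 0.945, 0.94, 0.93, 0.91, 0.85])
    alpha = np.log(tail / (1 - tail))
    return TrueModel(spec=spec, builder=builder, alpha=alpha, beta=beta,
                     shapes=shapes)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A generated cohort plus its retained ground truth."""

    baseline: pd.DataFrame           # patient_id, index_date, age, chads_vasc
    dispensing: pd.DataFrame
    hospital: pd.DataFrame
    windows: pd.DataFrame            # ground-truth windowed adherence, 1..horizon
    coverage: dict                   # patient_id -> bool day vector (drug cover)
    truth: TrueModel
    seed: int

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(out / "baseline.csv", index=False)
        self.dispensing.to_csv(out / "dispensing.csv", index=False)
        self.hospital.to_csv(out / "hospital.csv", index=False)
        self.windows.to_csv(out / "windows_truth.csv", index=False)
        self.truth.to_json(out / "truth.json", seed=self.seed)


# marginal parameters of the cohort (set to the published cohort profile)
_AGE_SKEW, _AGE_LOC, _AGE_SCALE = 1.5, 71.5, 12.0
_AGE_RANGE = (45.0, 99.0)
_SCORE_P = np.array([1.4, 7.5, 16.0, 23.0, 21.0, 17.0, 9.9, 4.0, 0.4])
_SCORE_P = _SCORE_P / _SCORE_P.sum()
_P_PERFECT = 0.50                    # share with no first-year gaps at all
_GAP_SHAPE, _GAP_SCALE = 1.2, 6.0    # Gamma gap propensity (days/window)
_GAP_MULT = (1.0, 1.8, 2.3, 2.7)     # per-window erosion of year-1 adherence
_HOSP_RATE = 0.10                    # stays per patient-year
_W1_MAX_GAP = 28                     # first window: at least ~2 months on drug


_AGE_DELTA = _AGE_SKEW / np.sqrt(1.0 + _AGE_SKEW**2)


def _draw_age(rng) -> float:
    # skew-normal via the two-normal representation, truncated by rejection
    lo, hi = _AGE_RANGE
    for _ in range(100):
        u0, u1 = rng.normal(size=2)
        z = _AGE_DELTA * abs(u0) + np.sqrt(1.0 - _AGE_DELTA**2) * u1
        a = _AGE_LOC + _AGE_SCALE * z
        if lo <= a <= hi:
            return float(np.round(a, 1))
    return float(np.clip(a, lo, hi))


def _year1_coverage(rng) -> np.ndarray:
    """Boolean drug-coverage vector for days 0..359."""
    lam = 0.0 if rng.random() < _P_PERFECT else rng.gamma(_GAP_SHAPE, _GAP_SCALE)
    cov = np.ones(4 * WINDOW, dtype=bool)
    for k in range(4):
        gap = int(min(rng.poisson(lam * _GAP_MULT[k]), WINDOW))
        if k == 0:
            gap = min(gap, _W1_MAX_GAP)
        if gap:
            start = int(rng.integers(0, WINDOW - gap + 1))
            cov[k * WINDOW + start : k * WINDOW + start + gap] = False
    return cov


def _coverage_for_state(state: int, rng) -> int:
    lo, hi = _STATE_DAY_RANGE[state]
    if state == 10 and rng.random() < 0.5:
        return 90
    return int(rng.integers(lo, hi + 1))


def _window_day_vector(covered: int, rng) -> np.ndarray:
    v = np.ones(WINDOW, dtype=bool)
    gap = WINDOW - covered
    if gap:
        start = int(rng.integers(0, WINDOW - gap + 1))
        v[start : start + gap] = False
    return v


def generate_dispensing(
    coverage: np.ndarray,
    rng,
    fill_size: int = 30,
    jitter: int = 7,
    switch_prob: float = 0.003,
) -> list[tuple[int, str, int]]:
    """Fills (dispense_day, drug_code, days_supplied) reconstructing coverage.

    Each maximal covered run is split into fills of at most ``fill_size``
    days; later fills are dispensed up to ``jitter`` days early (the
    carry-over rule shifts them forward again, so the reconstruction is
    exact), and the agent occasionally switches to exercise pooling
    (the default per-fill rate yields roughly one switcher in eight
    patients over five years of full coverage).  Empty coverage yields
    no records.
    """
    coverage = np.asarray(coverage, dtype=bool)
    fills = []
    drug = DRUGS[int(rng.integers(0, 3))]
    d = np.flatnonzero(coverage)
    if d.size == 0:
        return fills
    # maximal runs of consecutive covered days
    breaks = np.flatnonzero(np.diff(d) > 1)
    run_starts = np.concatenate([[d[0]], d[breaks + 1]])
    run_ends = np.concatenate([d[breaks] + 1, [d[-1] + 1]])
    for s, e in zip(run_starts, run_ends):
        remaining = int(e - s)
        eff_end = int(s)              # effective end of supply within the run
        prev_day = -1
        while remaining > 0:
            supply = min(fill_size, remaining)
            day = eff_end if eff_end == s else max(
                int(s), eff_end - int(rng.integers(0, jitter + 1)), prev_day + 1
            )
            if rng.random() < switch_prob:
                drug = DRUGS[int(rng.integers(0, len(DRUGS)))]
            fills.append((int(day), drug, int(supply)))
            prev_day = day
            eff_end += supply
            remaining -= supply
    return fills


def generate_cohort(
    n: int,
    true_model: TrueModel | None = None,
    seed: int = 0,
    horizon: int = 20,
    index_year_start: str = "2015-01-01",
    with_claims: bool = True,
) -> SyntheticCohort:
    """Generate a cohort of ``n`` patients with retained ground truth.

    Windows 1-4 arise from simulated day-level coverage plus hospital
    stays; their states follow the same gap-adjustment / hospital-credit
    / binning rules the PDC engine applies, computed here independently
    by day-set arithmetic.  Windows 5..horizon are drawn sequentially
    from ``true_model``, then converted back into day-level coverage and
    claims so the whole 5-year record round-trips through the engine.
    ``with_claims=False`` skips the claim-level reconstruction (the
    windowed ground truth is unchanged), which is what simulation
    studies of the model-fitting stage need.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tm = true_model if true_model is not None else default_true_model()
    K = tm.n_states
    t0 = pd.Timestamp(index_year_start)

    ages = np.empty(n)
    scores = np.empty(n, dtype=int)
    index_dates = []
    hosp_rows = []
    cover_y1 = []
    hosp_mask = []
    state_u = np.empty((n, horizon - 4))
    rngs = []                         # per-patient streams reused for claims
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        rngs.append(rng)
        ages[i] = _draw_age(rng)
        scores[i] = int(rng.choice(np.arange(1, 10), p=_SCORE_P))
        index_dates.append(t0 + pd.Timedelta(days=int(rng.integers(0, 365))))
        cov = _year1_coverage(rng)
        cover_y1.append(cov)
        hm = np.zeros(4 * WINDOW, dtype=bool)
        if rng.random() < _HOSP_RATE:
            dur = int(rng.integers(3, 15))
            admit = int(rng.integers(0, 4 * WINDOW - dur))
            hm[admit : admit + dur + 1] = True   # discharge day included
            hosp_rows.append((i, admit, admit + dur))
        hosp_mask.append(hm)
        state_u[i] = rng.random(horizon - 4)

    # ground-truth windows 1-4 (day-set arithmetic, union hospital credit)
    cov_w = np.empty((n, 4), dtype=int)
    hos_w = np.empty((n, 4), dtype=int)
    for i in range(n):
        for k in range(4):
            sl = slice(k * WINDOW, (k + 1) * WINDOW)
            c = cover_y1[i][sl]
            h = hosp_mask[i][sl]
            cov_w[i, k] = int(c.sum())
            hos_w[i, k] = int((h & ~c).sum())
    days_w = np.minimum(cov_w + hos_w, WINDOW)
    states14 = np.empty((n, 4), dtype=int)
    for k in range(4):
        pct = 100.0 * days_w[:, k] / WINDOW
        states14[:, k] = np.where(pct >= 90, 10, (pct // 10).astype(int) + 1)

    # windows 5..horizon from the true transition model (batched design)
    windows = np.arange(5, horizon + 1)
    T = len(windows)
    rows = pd.DataFrame({
        "age": np.repeat(ages, T * K),
        "chads_vasc": np.repeat(scores.astype(float), T * K),
        **{f"days_w{k+1}": np.repeat(days_w[:, k].astype(float), T * K)
           for k in range(4)},
        "time": np.tile(np.repeat(windows.astype(float), K), n),
        "y_prev": np.tile(np.arange(1, K + 1), n * T),
    })
    X = tm.builder.transform(rows)
    P_all = probs_from_design(tm.alpha, tm.beta, X, K).reshape(n, T, K, K)
    states = np.empty((n, T), dtype=int)
    cur = states14[:, 3].copy()
    for t in range(T):
        rowsP = P_all[np.arange(n), t, cur - 1]        # (n, K)
        cdf = np.cumsum(rowsP, axis=1)
        cur = 1 + (state_u[:, t][:, None] > cdf).sum(axis=1).astype(int)
        cur = np.clip(cur, 1, K)
        states[:, t] = cur

    # late coverage consistent with the drawn states; then claims
    disp_rows = []
    coverage_full = {}
    win_rows = []
    for i in range(n):
        rng = rngs[i]
        late = np.zeros((horizon - 4) * WINDOW, dtype=bool)
        late_cov = np.empty(T, dtype=int)
        for t in range(T):
            c = _coverage_for_state(states[i, t], rng)
            late_cov[t] = c
            late[t * WINDOW : (t + 1) * WINDOW] = _window_day_vector(c, rng)
        full = np.concatenate([cover_y1[i], late])
        coverage_full[i] = full
        if with_claims:
            for day, drug, supply in generate_dispensing(full, rng):
                disp_rows.append(
                    (i, (index_dates[i] + pd.Timedelta(days=day)).date(),
                     drug, supply))
        for k in range(4):
            pdc = min(int(days_w[i, k]), WINDOW) / WINDOW
            win_rows.append((i, k + 1, int(cov_w[i, k]), int(hos_w[i, k]),
                             pdc, int(states14[i, k])))
        for t in range(T):
            pdc = late_cov[t] / WINDOW
            win_rows.append((i, int(windows[t]), int(late_cov[t]), 0, pdc,
                             int(states[i, t])))

    baseline = pd.DataFrame({
        "patient_id": np.arange(n),
        "index_date": [d.date() for d in index_dates],
        "age": ages,
        "chads_vasc": scores,
    })
    dispensing = pd.DataFrame(
        disp_rows, columns=["patient_id", "dispense_date", "drug_code",
                            "days_supplied"],
    )
    hospital = pd.DataFrame(
        [
            (pid, (index_dates[pid] + pd.Timedelta(days=a)).date(),
             (index_dates[pid] + pd.Timedelta(days=d)).date())
            for pid, a, d in hosp_rows
        ],
        columns=["patient_id", "admit_date", "discharge_date"],
    )
    windows_df = pd.DataFrame(
        win_rows,
        columns=["patient_id", "window_index", "covered_days",
                 "hospital_days", "pdc", "state"],
    )
    return SyntheticCohort(
        baseline=baseline, dispensing=dispensing, hospital=hospital,
        windows=windows_df, coverage=coverage_full, truth=tm, seed=seed,
    )


def simulate_trajectories(
    true_model: TrueModel,
    covariates: dict,
    initial_state: int,
    n_sims: int,
    seed: int = 0,
    windows=None,
):
    """Empirical occupancy frequencies from forward-simulated chains.

    The Monte-Carlo oracle for the analytic occupancy recursion: per-cell
    standard error is at most 0.5/sqrt(n_sims).
    """
    from .sop import SOPMatrix

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    K = true_model.n_states
    if not 1 <= initial_state <= K:
        raise ValueError("initial_state outside range")
    if windows is None:
        windows = np.arange(5, 21)
    windows = np.asarray(windows)
    P = true_model.transition_matrices(covariates, windows)
    cdf = np.cumsum(P, axis=2)
    rng = np.random.default_rng(seed)
    cur = np.full(n_sims, initial_state, dtype=int)
    freqs = np.empty((len(windows), K))
    for t in range(len(windows)):
        u = rng.random(n_sims)
        cur = 1 + (u[:, None] > cdf[t, cur - 1]).sum(axis=1)
        cur = np.clip(cur, 1, K)
        freqs[t] = np.bincount(cur, minlength=K + 1)[1:] / n_sims
    return SOPMatrix(patient_id=None, windows=windows, probs=freqs)
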