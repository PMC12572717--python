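"""First-order proportional-odds Markov transition model.

The ordinal adherence state :math:`Y_t \\in \\{1..K\\}` at each 90-day
window is regressed on the state at the previous window, time, and
baseline covariates through a cumulative-logit model with proportional
odds:

.. math::

    P(Y_t \\ge j \\mid x) = \\mathrm{logit}^{-1}(\\alpha_j + x^\\top\\beta),
    \\qquad j = 2, \\dots, K,

with :math:`\\alpha_2 > \\alpha_3 > \\dots > \\alpha_K` so cumulative
probabilities are monotone.  Higher linear predictor means higher
adherence states, so positive coefficients correspond to better
adherence.  The model is fitted by Newton-Raphson with step halving on
the exact log-likelihood; the observed-information matrix at the
optimum supplies the coefficient covariance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .design import DesignBuilder, ModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "build_transition_table",
    "neg_loglik",
    "neg_loglik_grad",
    "neg_loglik_hess",
    "fit",
    "POFit",
    "transition_probs",
    "aic",
    "lr_test",
    "model_ladder",
    "ladder_specs",
    "partial_effect_curve",
]


def build_transition_table(
    windows: pd.DataFrame,
    baseline: pd.DataFrame,
    first_outcome_window: int = 5,
    horizon: int = 20,
) -> pd.DataFrame:
    """One row per (patient, outcome window t in 5..horizon).

    Columns: patient_id, time (window index t), y (state at t), y_prev
    (state at t-1), age, chads_vasc, days_w1..days_w4 (covered +
    credited hospital days of windows 1-4, capped at 90).  Patients
    missing any window 1..horizon are dropped with a log entry.
    """
    need = list(range(1, horizon + 1))
    state = windows.pivot(index="patient_id", columns="window_index",
                          values="state")
    missing_cols = [c for c in need if c not in state.columns]
    for c in missing_cols:
        state[c] = np.nan
    state = state[need]
    complete = state.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning(
            "build_transition_table: %d patients missing windows; dropped",
            n_dropped,
        )
    state = state[complete]
    covered = windows.pivot(index="patient_id", columns="window_index",
                            values="covered_days").reindex(state.index)
    hosp = windows.pivot(index="patient_id", columns="window_index",
                         values="hospital_days").reindex(state.index)
    base = baseline.set_index("patient_id").reindex(state.index)
    days = {
        f"days_w{k}": np.minimum(covered[k] + hosp[k], 90).astype(int)
        for k in range(1, 5)
    }
    parts = []
    for t in range(first_outcome_window, horizon + 1):
        parts.append(pd.DataFrame({
            "patient_id": state.index,
            "time": t,
            "y": state[t].astype(int).to_numpy(),
            "y_prev": state[t - 1].astype(int).to_numpy(),
            "age": base["age"].astype(float).to_numpy(),
            "chads_vasc": base["chads_vasc"].astype(float).to_numpy(),
            **{k: v.to_numpy() for k, v in days.items()},
        }))
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["patient_id", "time"], kind="stable",
                           ignore_index=True)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def neg_loglik(theta, X, y, n_states) -> float:
    """Negative log-likelihood of the cumulative-logit model.

    ``theta`` packs (alpha_2..alpha_K, beta).  Unordered intercepts
    produce non-positive category probabilities and return +inf (a
    barrier), never a silent NaN.
    """
    K = n_states
    alpha = theta[: K - 1]
    beta = theta[K - 1 :]
    if np.any(np.diff(alpha) >= 0):
        return np.inf
    eta = X @ beta
    u, v, *_ = _uv_parts(alpha, eta, y, K)
    p = u - v
    if np.any(p <= 0):
        return np.inf
    return -float(np.sum(np.log(p)))


def _uv_parts(alpha, eta, y, K):
    """Cumulative probs and their logistic derivatives per observation."""
    idx_u = y - 2          # alpha index for P(Y>=y); invalid when y==1
    idx_v = y - 1          # alpha index for P(Y>=y+1); invalid when y==K
    has_u = y >= 2
    has_v = y <= K - 1
    u = np.ones_like(eta)
    v = np.zeros_like(eta)
    u[has_u] = expit(alpha[idx_u[has_u]] + eta[has_u])
    v[has_v] = expit(alpha[idx_v[has_v]] + eta[has_v])
    du = u * (1 - u) * has_u     # d u / d eta (0 where u is constant 1)
    dv = v * (1 - v) * has_v
    return u, v, du, dv, idx_u, idx_v, has_u, has_v


def neg_loglik_grad(theta, X, y, n_states) -> np.ndarray:
    """Analytic gradient of :func:`neg_loglik`."""
    K = n_states
    alpha = theta[: K - 1]
    beta = theta[K - 1 :]
    eta = X @ beta
    u, v, du, dv, idx_u, idx_v, has_u, has_v = _uv_parts(alpha, eta, y, K)
    p = u - v
    with np.errstate(divide="ignore", invalid="ignore"):
        A = du / p              # dlogp/d eta_u  (NaN at infeasible theta)
        B = dv / p
    g_alpha = np.zeros(K - 1)
    np.add.at(g_alpha, idx_u[has_u], A[has_u])
    np.add.at(g_alpha, idx_v[has_v], -B[has_v])
    g_beta = X.T @ (A - B)
    return -np.concatenate([g_alpha, g_beta])


def neg_loglik_hess(theta, X, y, n_states) -> np.ndarray:
    """Analytic Hessian of :func:`neg_loglik` (observed information)."""
    K = n_states
    p_dim = X.shape[1]
    alpha = theta[: K - 1]
    beta = theta[K - 1 :]
    eta = X @ beta
    u, v, du, dv, idx_u, idx_v, has_u, has_v = _uv_parts(alpha, eta, y, K)
    p = u - v
    with np.errstate(divide="ignore", invalid="ignore"):
        A = du / p
        B = dv / p
        ddu = du * (1 - 2 * u)  # second logistic derivative wrt eta
        ddv = dv * (1 - 2 * v)
        # d2 logp / d eta_a^2, d eta_b^2, cross
        Laa = ddu / p - A ** 2
        Lbb = -ddv / p - B ** 2
        Lab = A * B
    n_par = (K - 1) + p_dim
    H = np.zeros((n_par, n_par))
    # alpha-alpha block
    np.add.at(H, (idx_u[has_u], idx_u[has_u]), Laa[has_u])
    np.add.at(H, (idx_v[has_v], idx_v[has_v]), Lbb[has_v])
    both = has_u & has_v
    np.add.at(H, (idx_u[both], idx_v[both]), Lab[both])
    np.add.at(H, (idx_v[both], idx_u[both]), Lab[both])
    # beta-beta block
    w = Laa + Lbb + 2 * Lab
    H[K - 1 :, K - 1 :] = X.T @ (X * w[:, None])
    # alpha-beta blocks
    ca = np.zeros((len(y), K - 1))
    rows = np.arange(len(y))
    ca[rows[has_u], idx_u[has_u]] += (Laa + Lab)[has_u]
    ca[rows[has_v], idx_v[has_v]] += (Lbb + Lab)[has_v]
    cross = X.T @ ca             # p_dim x (K-1)
    H[K - 1 :, : K - 1] = cross
    H[: K - 1, K - 1 :] = cross.T
    return -H


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class POFit:
    """A fitted proportional-odds Markov transition model."""

    spec: ModelSpec
    builder: DesignBuilder
    alpha: np.ndarray            # K-1 ordered intercepts (for Y >= j, j=2..K)
    beta: np.ndarray
    loglik: float
    vcov: np.ndarray
    n_obs: int
    converged: bool
    column_names: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.alpha) + len(self.beta)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta])

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    # -- serialization ---------------------------------------------------
    def to_json(self, path) -> None:
        """Serialize everything needed to reproduce predictions exactly."""
        d = {
            "spec": self.spec.to_dict(),
            "fitted_knots": {k: list(map(float, v))
                             for k, v in self.builder.knots_.items()},
            "fitted_centers": {k: float(v)
                               for k, v in self.builder.centers_.items()},
            "prev_levels": (None if self.builder.prev_levels_ is None
                            else [int(l) for l in self.builder.prev_levels_]),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "loglik": self.loglik,
            "vcov": self.vcov.tolist(),
            "n_obs": self.n_obs,
            "converged": self.converged,
            "column_names": self.column_names,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "POFit":
        with open(path) as fh:
            d = json.load(fh)
        spec = ModelSpec.from_dict(d["spec"])
        builder = DesignBuilder(spec)
        builder.knots_ = {k: np.asarray(v, float)
                          for k, v in d["fitted_knots"].items()}
        builder.centers_ = {k: float(v) for k, v in d["fitted_centers"].items()}
        builder.prev_levels_ = (None if d["prev_levels"] is None
                                else np.asarray(d["prev_levels"]))
        builder.column_names_ = d["column_names"]
        return cls(
            spec=spec,
            builder=builder,
            alpha=np.asarray(d["alpha"]),
            beta=np.asarray(d["beta"]),
            loglik=float(d["loglik"]),
            vcov=np.asarray(d["vcov"]),
            n_obs=int(d["n_obs"]),
            converged=bool(d["converged"]),
            column_names=d["column_names"],
        )


def _start_values(y, K, p_dim) -> np.ndarray:
    """Intercept-only start: marginal cumulative log-odds, beta = 0."""
    counts = np.bincount(y, minlength=K + 1)[1:]
    n = counts.sum()
    # P(Y >= j) for j = 2..K, clipped away from 0/1
    tail = np.cumsum(counts[::-1])[::-1] / n
    q = np.clip(tail[1:], 1e-6, 1 - 1e-6)
    alpha0 = np.log(q / (1 - q))
    # enforce strict ordering in degenerate cases
    for i in range(1, len(alpha0)):
        if alpha0[i] >= alpha0[i - 1]:
            alpha0[i] = alpha0[i - 1] - 1e-6
    return np.concatenate([alpha0, np.zeros(p_dim)])


def fit(
    spec: ModelSpec,
    transitions: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> POFit:
    """Maximum-likelihood fit by Newton-Raphson with step halving.

    Starts at the intercept-only solution (marginal cumulative
    log-odds, beta = 0), which is always feasible; the intercept
    ordering is maintained by the +inf likelihood barrier during line
    search.  Convergence requires gradient sup-norm < tol*(1+|loglik|).
    Non-convergence or separation yields a flagged fit, not an
    exception.  The procedure involves no randomness.
    """
    builder = DesignBuilder(spec)
    X = builder.fit_transform(transitions)
    y = transitions["y"].to_numpy(int)
    K = spec.n_states
    if len(np.unique(y)) < 2:
        raise ValueError("need observations in at least 2 outcome categories")
    theta = _start_values(y, K, X.shape[1])
    f = neg_loglik(theta, X, y, K)
    converged = False
    for _ in range(max_iter):
        g = neg_loglik_grad(theta, X, y, K)
        if np.max(np.abs(g)) < tol * (1 + abs(f)):
            converged = True
            break
        H = neg_loglik_hess(theta, X, y, K)
        step = _newton_step(H, g)
        # backtracking line search against the barrier
        t_ls, ok = 1.0, False
        for _ in range(40):
            cand = theta - t_ls * step
            f_new = neg_loglik(cand, X, y, K)
            if f_new < f:
                theta, f, ok = cand, f_new, True
                break
            t_ls *= 0.5
        if not ok:
            break
    else:
        g = neg_loglik_grad(theta, X, y, K)
        converged = bool(np.max(np.abs(g)) < tol * (1 + abs(f)))
    if not converged:
        g = neg_loglik_grad(theta, X, y, K)
        converged = bool(np.max(np.abs(g)) < np.sqrt(tol) * (1 + abs(f)))
        if not converged:
            logger.warning("fit did not converge (grad sup-norm %.3g)",
                           np.max(np.abs(g)))
    H = neg_loglik_hess(theta, X, y, K)
    vcov = _safe_inverse(H)
    return POFit(
        spec=spec,
        builder=builder,
        alpha=theta[: K - 1].copy(),
        beta=theta[K - 1 :].copy(),
        loglik=-f,
        vcov=vcov,
        n_obs=len(y),
        converged=converged,
        column_names=list(builder.column_names_),
    )


def _newton_step(H, g) -> np.ndarray:
    """Solve H s = g, adding a ridge if H is not positive definite."""
    ridge = 0.0
    for _ in range(8):
        try:
            Hr = H + ridge * np.eye(len(g)) if ridge else H
            L = np.linalg.cholesky(Hr)
            s = np.linalg.solve(L.T, np.linalg.solve(L, g))
            return s
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10, 1e-6 * (1 + np.abs(np.diag(H)).max()))
    return g / (1 + np.abs(np.diag(H)).max())


def _safe_inverse(H) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("observed information singular; pseudo-inverse vcov")
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# predictions and comparisons
# ---------------------------------------------------------------------------

def probs_from_design(alpha, beta, X, n_states) -> np.ndarray:
    """Category probabilities (rows sum to 1) for design rows X."""
    eta = X @ beta
    cum = expit(alpha[None, :] + eta[:, None])          # P(Y>=j), j=2..K
    cum_full = np.hstack([np.ones((len(eta), 1)), cum, np.zeros((len(eta), 1))])
    return cum_full[:, :-1] - cum_full[:, 1:]


def transition_probs(fit_: POFit, covariates: dict, y_prev: int, time: float) -> np.ndarray:
    """One-step transition distribution over states for one subject.

    ``covariates`` supplies the baseline variables of the model spec
    (e.g. age, chads_vasc, days_w1..days_w4).
    """
    K = fit_.spec.n_states
    if not 1 <= y_prev <= K:
        raise ValueError(f"y_prev {y_prev} outside 1..{K}")
    row = dict(covariates)
    row["y_prev"] = y_prev
    row["time"] = time
    X = fit_.builder.transform(pd.DataFrame([row]))
    return probs_from_design(fit_.alpha, fit_.beta, X, K)[0]


def aic(fit_: POFit) -> float:
    return -2.0 * fit_.loglik + 2.0 * fit_.n_params


def lr_test(fit_nested: POFit, fit_full: POFit):
    """Likelihood-ratio test of a nested model against a richer one."""
    df = fit_full.n_params - fit_nested.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters")
    stat = 2.0 * (fit_full.loglik - fit_nested.loglik)
    if stat < 0:
        logger.warning("LR statistic negative (%.3g); models may not be nested", stat)
        stat = max(stat, 0.0)
    p = stats.chi2.sf(stat, df)
    return stat, df, p


def ladder_specs(n_states: int = 10, knots: dict | None = None,
                 centers: dict | None = None) -> dict[str, ModelSpec]:
    """The model-comparison ladder: basic model and its variants.

    basic = age + score + four first-year windows (all restricted cubic
    splines) + previous state + time; the candidate set adds time
    interactions on windows 3-4, drops covariates, or drops windows.
    """
    knots = knots or {}
    centers = centers or {}

    def mk(vars_, inter=()):
        return ModelSpec(
            terms=[(v, "rcs4") for v in vars_],
            interactions=[(v, "time") for v in inter],
            knots={k: v for k, v in knots.items() if k in vars_ or k == "time"},
            centers=centers,
            n_states=n_states,
        )

    w = ["days_w1", "days_w2", "days_w3", "days_w4"]
    return {
        "basic": mk(["age", "chads_vasc"] + w),
        "basic+time_interaction_w3_w4": mk(["age", "chads_vasc"] + w,
                                           inter=["days_w3", "days_w4"]),
        "two_windows": mk(["age", "chads_vasc", "days_w1", "days_w2"]),
        "no_age": mk(["chads_vasc"] + w),
        "no_score": mk(["age"] + w),
        "no_baseline": mk(w),
        "drop_w4": mk(["age", "chads_vasc", "days_w1", "days_w2", "days_w3"]),
        "drop_w3": mk(["age", "chads_vasc", "days_w1", "days_w2", "days_w4"]),
        "drop_w1": mk(["age", "chads_vasc", "days_w2", "days_w3", "days_w4"]),
        "drop_w2": mk(["age", "chads_vasc", "days_w1", "days_w3", "days_w4"]),
    }


def model_ladder(transitions: pd.DataFrame, n_states: int = 10,
                 knots: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Fit the comparison ladder and rank by AIC.

    Returns (table, fits).  The table has one row per candidate with
    AIC and the likelihood-ratio test against the basic model (for the
    richer interaction model the test direction is reversed so the
    statistic stays non-negative); the minimum-AIC spec is flagged as
    final.  Non-converging members are marked and the ladder continues.
    """
    specs = ladder_specs(n_states=n_states, knots=knots)
    fits, rows = {}, []
    basic = fit(specs["basic"], transitions)
    fits["basic"] = basic
    for name, spec in specs.items():
        f = basic if name == "basic" else fit(spec, transitions)
        fits[name] = f
        if name == "basic":
            stat = df = p = np.nan
        elif f.n_params > basic.n_params:
            stat, df, p = lr_test(basic, f)
        else:
            stat, df, p = lr_test(f, basic)
        rows.append(dict(model=name, aic=aic(f), loglik=f.loglik,
                         n_params=f.n_params, lr_stat=stat, lr_df=df,
                         lr_p=p, converged=f.converged))
    table = pd.DataFrame(rows)
    table["final"] = table["aic"] == table.loc[table["converged"], "aic"].min()
    return table, fits


def partial_effect_curve(fit_: POFit, variable: str, grid) -> pd.DataFrame:
    """Log-odds effect of one predictor with others held at their centers.

    effect(g) = x(g).beta - x(ref).beta where ref is the variable's
    centering constant; the 95% CI comes from the delta method.  Because
    every other variable sits exactly at its centering constant (and the
    previous state at its reference level), the contrast reduces to the
    variable's own (and its interaction's) columns.
    """
    if variable not in [v for v, _ in fit_.spec.terms]:
        raise ValueError(f"{variable!r} not in model spec")
    grid = np.asarray(grid, dtype=float)
    b = fit_.builder
    base_row = {v: b.centers_[v] for v, _ in fit_.spec.terms}
    base_row["time"] = b.centers_["time"]
    base_row["y_prev"] = fit_.spec.n_states
    rows = []
    for g in grid:
        r = dict(base_row)
        r[variable] = g
        rows.append(r)
    X = b.transform(pd.DataFrame(rows))
    X0 = b.transform(pd.DataFrame([base_row]))
    D = X - X0
    eff = D @ fit_.beta
    v_beta = fit_.vcov[len(fit_.alpha):, len(fit_.alpha):]
    se = np.sqrt(np.einsum("ij,jk,ik->i", D, v_beta, D))
    z = stats.norm.ppf(0.975)
    return pd.DataFrame({
        "grid": grid, "effect": eff,
        "lower": eff - z * se, "upper": eff + z * se,
    })
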