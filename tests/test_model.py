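import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from pdcmarkov.design import DesignBuilder, ModelSpec
from pdcmarkov.model import (
    POFit,
    aic,
    build_transition_table,
    fit,
    lr_test,
    model_ladder,
    neg_loglik,
    neg_loglik_grad,
    neg_loglik_hess,
    partial_effect_curve,
    transition_probs,
)
from pdcmarkov.synthetic import generate_cohort


class TestTransitionTable:
    def test_hand_built_fixture(self):
        rows = []
        # patient A perfectly adherent, patient B at state 9 in window 6
        for pid, states in [("A", {t: 10 for t in range(1, 21)}),
                            ("B", {**{t: 10 for t in range(1, 21)}, 6: 9})]:
            for t, s in states.items():
                c = 90 if s == 10 else 81
                rows.append((pid, t, c, 0, c / 90, s))
        windows = pd.DataFrame(
            rows, columns=["patient_id", "window_index", "covered_days",
                           "hospital_days", "pdc", "state"])
        base = pd.DataFrame({"patient_id": ["A", "B"], "age": [70, 80],
                             "chads_vasc": [3, 6]})
        t = build_transition_table(windows, base)
        assert len(t) == 32
        a = t[t.patient_id == "A"]
        assert (a.y == 10).all() and (a.y_prev == 10).all()
        assert (a[[f"days_w{k}" for k in range(1, 5)]] == 90).all().all()
        b = t[t.patient_id == "B"]
        assert b.loc[b.time == 6, "y"].item() == 9
        assert b.loc[b.time == 7, "y_prev"].item() == 9

    def test_incomplete_patient_dropped(self):
        windows = pd.DataFrame({
            "patient_id": ["A"] * 19, "window_index": range(1, 20),
            "covered_days": 90, "hospital_days": 0, "pdc": 1.0, "state": 10,
        })
        base = pd.DataFrame({"patient_id": ["A"], "age": [70],
                             "chads_vasc": [3]})
        assert len(build_transition_table(windows, base)) == 0


def _sim_ordinal(n, n_states, beta, seed=0):
    """Simple cumulative-logit data with a couple of covariates."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    eta = beta[0] * x1 + beta[1] * x2
    alpha = np.linspace(2.0, -2.0, n_states - 1)
    cum = expit(alpha[None, :] + eta[:, None])
    full = np.hstack([np.ones((n, 1)), cum, np.zeros((n, 1))])
    p = full[:, :-1] - full[:, 1:]
    y = np.array([rng.choice(n_states, p=pi / pi.sum()) for pi in p]) + 1
    # y_prev and time vary but carry no signal (true coefficient 0)
    return pd.DataFrame({
        "y": y, "y_prev": rng.integers(1, n_states + 1, n),
        "time": rng.integers(0, 4, n).astype(float), "x1": x1, "x2": x2,
    })


def _simple_spec(n_states):
    return ModelSpec(terms=[("x1", "linear"), ("x2", "linear")],
                     prev_state_encoding="linear", n_states=n_states)


class TestLikelihood:
    def test_two_states_equals_binary_logistic_loglik(self):
        t = _sim_ordinal(500, 2, [0.8, -0.5], seed=1)
        spec = _simple_spec(2)
        b = DesignBuilder(spec)
        X = b.fit_transform(t)
        y = t["y"].to_numpy()
        theta = np.array([0.3, 0.7, -0.2, 0.0, 0.0])
        # binary logistic with outcome I(y == 2): P = expit(a + x.b)
        eta = theta[0] + X @ theta[1:]
        ll_bin = np.sum(np.where(y == 2, -np.logaddexp(0, -eta),
                                 -np.logaddexp(0, eta)))
        assert neg_loglik(theta, X, y, 2) == pytest.approx(-ll_bin)

    def test_intercept_only_equals_multinomial_entropy(self):
        rng = np.random.default_rng(2)
        y = rng.integers(1, 11, 2000)
        X = np.zeros((2000, 1))
        counts = np.bincount(y, minlength=11)[1:]
        tail = np.cumsum(counts[::-1])[::-1] / len(y)
        alpha = logit(tail[1:])
        theta = np.concatenate([alpha, [0.0]])
        expected = -np.sum(counts * np.log(counts / len(y)))
        assert neg_loglik(theta, X, y, 10) == pytest.approx(expected)

    def test_unordered_intercepts_hit_barrier(self):
        X = np.zeros((5, 1))
        y = np.array([1, 2, 3, 2, 1])
        theta = np.array([0.0, 1.0, 0.0])  # alpha increasing: infeasible
        assert neg_loglik(theta, X, y, 3) == np.inf

    def test_single_observation_hand_computed(self):
        X = np.array([[0.5]])
        y = np.array([10])
        alpha = np.linspace(3, -3, 9)
        theta = np.concatenate([alpha, [2.0]])
        p = expit(alpha[-1] + 0.5 * 2.0)  # P(Y >= 10)
        assert neg_loglik(theta, X, y, 10) == pytest.approx(-np.log(p))

    def test_gradient_matches_central_differences(self):
        t = _sim_ordinal(300, 5, [0.6, -0.4], seed=3)
        spec = _simple_spec(5)
        X = DesignBuilder(spec).fit_transform(t)
        y = t["y"].to_numpy()
        rng = np.random.default_rng(4)
        for _ in range(20):
            alpha = np.sort(rng.normal(0, 1.5, 4))[::-1]
            alpha -= np.arange(4) * 0.05  # keep strictly decreasing
            theta = np.concatenate([alpha, rng.normal(0, 0.5, X.shape[1])])
            if not np.isfinite(neg_loglik(theta, X, y, 5)):
                continue
            g = neg_loglik_grad(theta, X, y, 5)
            eps = 1e-6
            gfd = np.empty_like(g)
            for i in range(len(theta)):
                e = np.zeros_like(theta)
                e[i] = eps
                gfd[i] = (neg_loglik(theta + e, X, y, 5)
                          - neg_loglik(theta - e, X, y, 5)) / (2 * eps)
            np.testing.assert_allclose(g, gfd, rtol=1e-5, atol=1e-6)

    def test_hessian_matches_gradient_differences(self):
        t = _sim_ordinal(200, 4, [0.5, 0.3], seed=5)
        spec = _simple_spec(4)
        X = DesignBuilder(spec).fit_transform(t)
        y = t["y"].to_numpy()
        theta = np.concatenate([[1.5, 0.0, -1.5],
                                np.array([0.2, -0.1, 0.0, 0.0])[: X.shape[1]]])
        H = neg_loglik_hess(theta, X, y, 4)
        eps = 1e-5
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = eps
            col = (neg_loglik_grad(theta + e, X, y, 4)
                   - neg_loglik_grad(theta - e, X, y, 4)) / (2 * eps)
            np.testing.assert_allclose(H[:, i], col, rtol=1e-4, atol=1e-4)


class TestFit:
    def test_binary_reduction_matches_glm(self):
        """With two outcome states the fit equals binary logistic
        regression (independent statsmodels GLM) to 1e-6."""
        import statsmodels.api as sm

        t = _sim_ordinal(2000, 2, [0.8, -0.5], seed=6)
        f = fit(_simple_spec(2), t)
        X = f.builder.transform(t)
        glm = sm.GLM((t["y"] == 2).astype(float),
                     sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(f.alpha[0], glm.params.iloc[0], atol=1e-6)
        np.testing.assert_allclose(f.beta[:2], glm.params.iloc[1:3], atol=1e-6)

    def test_intercept_only_mle_is_marginal_logits(self):
        """With no covariates the MLE intercepts are the empirical
        marginal cumulative log-odds (closed form)."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(7)
        y = rng.integers(1, 7, 4000)
        X = np.zeros((4000, 0))
        counts = np.bincount(y, minlength=7)[1:]
        tail = np.cumsum(counts[::-1])[::-1] / len(y)
        expect = logit(tail[1:])
        res = minimize(neg_loglik, expect + 0.3 * np.linspace(1, -1, 5),
                       args=(X, y, 6), jac=neg_loglik_grad, method="BFGS",
                       options={"gtol": 1e-10})
        np.testing.assert_allclose(res.x, expect, atol=1e-6)

    def test_null_data_gives_small_z_scores(self):
        t = _sim_ordinal(4000, 6, [0.0, 0.0], seed=7)
        f = fit(_simple_spec(6), t)
        counts = np.bincount(t["y"], minlength=7)[1:]
        tail = np.cumsum(counts[::-1])[::-1] / len(t)
        np.testing.assert_allclose(f.alpha, logit(tail[1:]), atol=0.2)
        z = f.beta / f.se()[5:]
        assert np.all(np.abs(z) < 3.5)

    def test_matches_statsmodels_ordered_model(self, transitions, fitted):
        """Independent check of the full 10-state fit against the
        statsmodels ordinal regression on the same design: our optimum
        must be a fixed point of their optimizer."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        X = fitted.builder.transform(transitions)
        om = OrderedModel(transitions["y"].to_numpy(), X, distr="logit")
        # their parameterization: P(Y<=j) = F(theta_j - x.beta) with
        # thresholds stored as (theta_1, log successive differences)
        theta = -fitted.alpha  # increasing since alpha is decreasing
        start = np.concatenate(
            [fitted.beta, [theta[0]], np.log(np.diff(theta))])
        res = om.fit(start_params=start, method="bfgs", disp=False,
                     maxiter=200)
        assert fitted.loglik >= res.llf - 1e-6
        np.testing.assert_allclose(fitted.beta, res.params[: X.shape[1]],
                                   atol=1e-4)

    def test_intercepts_strictly_decreasing(self, fitted):
        assert np.all(np.diff(fitted.alpha) < 0)

    def test_constant_column_absorbed_by_intercepts(self):
        """Shifting a covariate changes intercepts, not probabilities."""
        t = _sim_ordinal(800, 4, [0.5, -0.3], seed=8)
        f1 = fit(_simple_spec(4), t)
        t2 = t.copy()
        t2["x1"] = t2["x1"] + 5.0  # centering removes the shift
        f2 = fit(_simple_spec(4), t2)
        p1 = transition_probs(f1, {"x1": 1.0, "x2": 0.5}, 1, 1.0)
        p2 = transition_probs(f2, {"x1": 6.0, "x2": 0.5}, 1, 1.0)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_estimation_error_shrinks_with_n(self, true_model):
        errs = []
        for n in (500, 5000):
            coh = generate_cohort(n, true_model, seed=99, with_claims=False)
            t = build_transition_table(coh.windows, coh.baseline)
            f = fit(true_model.spec, t)
            errs.append(np.mean(np.abs(f.beta - true_model.beta)))
        assert errs[1] < errs[0]

    def test_serialization_round_trip(self, fitted, transitions, tmp_path):
        path = tmp_path / "fit.json"
        fitted.to_json(path)
        back = POFit.from_json(path)
        covs = {v: transitions[v].iloc[0] for v, _ in fitted.spec.terms}
        p1 = transition_probs(fitted, covs, 9, 12.0)
        p2 = transition_probs(back, covs, 9, 12.0)
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestTransitionProbs:
    def test_hand_computed_logistic_differences(self, fitted, transitions):
        covs = {v: transitions[v].iloc[5] for v, _ in fitted.spec.terms}
        p = transition_probs(fitted, covs, 10, 8.0)
        row = dict(covs, y_prev=10, time=8.0)
        X = fitted.builder.transform(pd.DataFrame([row]))
        eta = (X @ fitted.beta).item()
        cum = expit(fitted.alpha + eta)
        expect = np.diff(-np.concatenate([[1.0], cum, [0.0]]))
        np.testing.assert_allclose(p, expect, atol=1e-12)

    def test_rows_sum_to_one(self, fitted, transitions):
        for i in [0, 100, 500]:
            covs = {v: transitions[v].iloc[i] for v, _ in fitted.spec.terms}
            p = transition_probs(fitted, covs, 3, 15.0)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (p >= 0).all()

    def test_cumulative_monotone_in_j(self, fitted, transitions):
        covs = {v: transitions[v].iloc[9] for v, _ in fitted.spec.terms}
        p = transition_probs(fitted, covs, 5, 10.0)
        cum = np.cumsum(p[::-1])[::-1]  # P(Y >= j)
        assert np.all(np.diff(cum) < 0)


class TestComparison:
    def test_aic_formula(self):
        f = POFit(spec=_simple_spec(3), builder=None,
                  alpha=np.array([1.0, -1.0]), beta=np.array([0.5, 0.2, 0.1]),
                  loglik=-100.0, vcov=np.eye(5), n_obs=10, converged=True)
        assert aic(f) == 210.0

    def test_identical_fits_lr_zero(self, fitted):
        import dataclasses

        bigger = dataclasses.replace(
            fitted, beta=np.append(fitted.beta, 0.0))
        stat, df, p = lr_test(fitted, bigger)
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_ladder_structure(self, transitions, true_model):
        table, fits = model_ladder(
            transitions, knots={k: v for k, v in true_model.spec.knots.items()})
        assert len(table) == 10
        assert table["final"].sum() == 1
        nested = table[table.model != "basic"]
        assert (nested["lr_stat"] >= 0).all()
        # every nested model has fewer parameters than basic
        basic_p = table.loc[table.model == "basic", "n_params"].item()
        inter_p = table.loc[table.model == "basic+time_interaction_w3_w4",
                            "n_params"].item()
        assert inter_p == basic_p + 6


class TestPartialEffects:
    def test_zero_coefficient_gives_flat_curve(self, true_model, transitions):
        import dataclasses

        f = fit(true_model.spec, transitions)
        f0 = dataclasses.replace(f, beta=np.zeros_like(f.beta))
        c = partial_effect_curve(f0, "age", np.linspace(60, 95, 20))
        assert np.abs(c["effect"]).max() == 0.0

    def test_linear_term_gives_straight_line(self):
        t = _sim_ordinal(600, 3, [0.7, 0.0], seed=9)
        f = fit(_simple_spec(3), t)
        c = partial_effect_curve(f, "x1", np.linspace(-2, 2, 10))
        slopes = np.diff(c["effect"]) / np.diff(c["grid"])
        np.testing.assert_allclose(slopes, f.beta[0], rtol=1e-10)

    def test_spline_curve_matches_design_multiplication(self, fitted):
        grid = np.linspace(0, 90, 50)
        c = partial_effect_curve(fitted, "days_w4", grid)
        b = fitted.builder
        base = {v: b.centers_[v] for v, _ in fitted.spec.terms}
        base["time"] = b.centers_["time"]
        base["y_prev"] = 10
        rows = [dict(base, days_w4=g) for g in grid]
        X = b.transform(pd.DataFrame(rows)) - b.transform(pd.DataFrame([base]))
        np.testing.assert_allclose(c["effect"], X @ fitted.beta, atol=1e-12)
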