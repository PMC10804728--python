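"""Six survival models: oracles, limit equivalences, tuning contract."""

import numpy as np
import pandas as pd
import pytest

from dosiofuse.coxutils import cox_partial_loglik
from dosiofuse.metrics import harrell_cindex
from dosiofuse.models import (
    CoxBoost, CoxNet, CoxPH, GLMBoost, MODEL_REGISTRY, RSFModel, STreeModel,
    default_grid, fit_coxph, make_model, predict_risk, tune,
)
from dosiofuse.phantom import simulate_cohort


@pytest.fixture(scope="module")
def small_cohort():
    beta = np.zeros(5)
    beta[0], beta[1] = 1.5, -1.0
    co = simulate_cohort([150, 150], beta, censor_rate=0.25, seed=21)
    return co.features, (co.time, co.event)


class TestCoxPH:
    def test_matches_bruteforce_partial_likelihood(self):
        # n=6, one binary covariate, no ties: grid-maximize the exact
        # partial likelihood and compare the coefficient to 1e-4
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, int)
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])

        def loglik(beta):
            # independent oracle: direct sum over risk sets
            ll = 0.0
            for i in range(6):
                risk = np.exp(beta * x[time >= time[i]])
                ll += beta * x[i] - np.log(risk.sum())
            return ll

        grid = np.arange(-5, 5, 1e-4)
        lls = [loglik(b) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        model = CoxPH().fit(pd.DataFrame({"x": x}), (time, event))
        assert model.coef_[0] == pytest.approx(beta_star, abs=1e-4)

    def test_null_covariate_small_coefficient(self):
        co = simulate_cohort([500], np.zeros(1), censor_rate=0.2, seed=3)
        model = CoxPH().fit(co.features, (co.time, co.event))
        se = model.fitter_.standard_errors_.iloc[0]
        assert abs(model.coef_[0]) < 2 * se

    def test_duplicated_row_changes_fit(self, small_cohort):
        X, (t, e) = small_cohort
        m1 = CoxPH().fit(X, (t, e))
        X2 = pd.concat([X, X.iloc[[0]]], ignore_index=True)
        m2 = CoxPH().fit(X2, (np.append(t, t[0]), np.append(e, e[0])))
        assert not np.allclose(m1.coef_, m2.coef_)


class TestCoxBoost:
    def test_zero_steps_null_model(self, small_cohort):
        X, y = small_cohort
        m = CoxBoost(n_steps=0).fit(X, y)
        assert not m.coef_.any()
        c = harrell_cindex(m.predict(X), *y)
        assert c == pytest.approx(0.5)

    def test_informative_coefficient_enters_first(self):
        beta = np.zeros(10)
        beta[0] = 2.0
        co = simulate_cohort([300], beta, censor_rate=0.2, seed=9)
        m = CoxBoost(n_steps=20).fit(co.features, (co.time, co.event))
        first_nonzero = np.nonzero(m.coef_path_[1])[0]
        assert list(first_nonzero) == [0]

    def test_coefficients_shrink_with_penalty(self, small_cohort):
        X, y = small_cohort
        norms = []
        for pen in (10.0, 100.0, 1000.0, 10000.0):
            m = CoxBoost(n_steps=50, penalty=pen).fit(X, y)
            norms.append(np.abs(m.coef_).sum())
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_training_likelihood_improves(self, small_cohort):
        X, y = small_cohort
        m = CoxBoost(n_steps=30).fit(X, y)
        t, e = y
        ll0 = cox_partial_loglik(t, e, np.zeros(len(t)))
        ll1 = cox_partial_loglik(t, e, X.to_numpy() @ m.coef_)
        assert ll1 > ll0

    def test_invalid_penalty_rejected(self, small_cohort):
        X, y = small_cohort
        with pytest.raises(ValueError, match="penalty"):
            CoxBoost(penalty=-5.0).fit(X, y)


class TestGLMBoost:
    def test_mstop_zero_null_model(self, small_cohort):
        X, y = small_cohort
        m = GLMBoost(mstop=0).fit(X, y)
        assert not m.coef_.any()

    def test_likelihood_nondecreasing_in_mstop(self, small_cohort):
        X, y = small_cohort
        t, e = y
        lls = []
        for mstop in (10, 50, 200, 1000):
            m = GLMBoost(mstop=mstop, nu=0.1).fit(X, y)
            lls.append(cox_partial_loglik(t, e, X.to_numpy() @ m.coef_))
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_converges_to_coxph(self):
        co = simulate_cohort([300], np.array([1.0, -0.7]), censor_rate=0.2, seed=5)
        X, y = co.features, (co.time, co.event)
        ref = CoxPH().fit(X, y).coef_
        m = GLMBoost(mstop=5000, nu=0.1).fit(X, y)
        assert np.abs(m.coef_ - ref).max() / np.abs(ref).max() < 0.05

    def test_bad_learning_rate_rejected(self, small_cohort):
        X, y = small_cohort
        with pytest.raises(ValueError, match="nu"):
            GLMBoost(nu=1.5).fit(X, y)


class TestCoxNet:
    def test_unpenalized_ridge_limit_matches_coxph(self):
        co = simulate_cohort([300], np.array([1.0, -0.6, 0.3, 0.0, 0.0]),
                             censor_rate=0.2, seed=7)
        X, y = co.features, (co.time, co.event)
        ref = CoxPH().fit(X, y).coef_
        m = CoxNet(alpha=0.0, lam=1e-8).fit(X, y)
        assert np.abs(m.coef_ - ref).max() / np.abs(ref).max() < 0.01

    def test_huge_lambda_all_zero(self, small_cohort):
        X, y = small_cohort
        m = CoxNet(alpha=1.0, lam=1e4).fit(X, y)
        assert not m.coef_.any()
        assert m.null_model_

    def test_lasso_path_sparsity_monotone(self, small_cohort):
        X, y = small_cohort
        nnz = []
        for frac in (0.0, 0.3, 0.6, 1.0):
            m = CoxNet(alpha=1.0, lam_frac=frac).fit(X, y)
            nnz.append(int(np.count_nonzero(m.coef_)))
        assert all(b >= a for a, b in zip(nnz, nnz[1:]))


class TestTreeModels:
    def test_perfect_binary_split(self):
        rng = np.random.default_rng(4)
        n = 200
        x = np.repeat([0.0, 1.0], n // 2)
        time = np.where(x > 0.5, rng.exponential(100, n), rng.exponential(2000, n))
        time = np.maximum(time, 0.1)
        event = np.ones(n, int)
        X = pd.DataFrame({"grp": x, "noise": rng.normal(size=n)})
        st = STreeModel(depth=2).fit(X, (time, event))
        root_feature = st.est_.tree_.feature[0]
        assert root_feature == 0
        from lifelines.statistics import logrank_test

        lr = logrank_test(time[x > 0.5], time[x <= 0.5],
                          event[x > 0.5], event[x <= 0.5])
        assert lr.p_value < 0.01

    def test_rsf_single_tree_reproducible(self, small_cohort):
        X, y = small_cohort
        a = RSFModel(n_trees=1, seed=5).fit(X, y).predict(X)
        b = RSFModel(n_trees=1, seed=5).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_rsf_recovers_planted_signal(self):
        beta = np.zeros(10)
        beta[:2] = [1.5, -1.5]
        co = simulate_cohort([400], beta, censor_rate=0.2, seed=12)
        m = RSFModel(n_trees=200, seed=1).fit(co.features, (co.time, co.event))
        c = harrell_cindex(m.predict(co.features), co.time, co.event)
        assert c > 0.75

    def test_rsf_rank_invariant_to_monotone_feature_rescale(self, small_cohort):
        X, y = small_cohort
        m1 = RSFModel(n_trees=50, seed=3).fit(X, y)
        X2 = X.copy()
        X2["f000"] = np.exp(X2["f000"])  # strictly monotone
        m2 = RSFModel(n_trees=50, seed=3).fit(X2, y)
        r1 = m1.predict(X)
        r2 = m2.predict(X2)
        assert np.corrcoef(r1, r2)[0, 1] > 0.98


class TestPredictContract:
    def test_coxph_risk_is_linear(self, small_cohort):
        X, y = small_cohort
        m = CoxPH().fit(X.iloc[:, :2], y)
        m.coef_ = np.array([1.0, 0.0])
        rows = X.iloc[:2, :2]
        risks = m.predict(rows)
        assert risks[0] - risks[1] == pytest.approx(
            rows.iloc[0, 0] - rows.iloc[1, 0])

    def test_identical_rows_identical_scores(self, small_cohort):
        X, y = small_cohort
        dup = pd.concat([X.iloc[[3]]] * 2, ignore_index=True)
        for name in MODEL_REGISTRY:
            m = make_model(name)
            m.fit(X, y)
            r = predict_risk(m, dup)
            assert r[0] == pytest.approx(r[1])

    def test_missing_column_named(self, small_cohort):
        X, y = small_cohort
        m = CoxPH().fit(X, y)
        with pytest.raises(ValueError, match="f000"):
            m.predict(X.drop(columns=["f000"]))

    def test_permuting_rows_leaves_fit_invariant(self, small_cohort):
        X, (t, e) = small_cohort
        m1 = CoxPH().fit(X, (t, e))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(t))
        m2 = CoxPH().fit(X.iloc[perm].reset_index(drop=True), (t[perm], e[perm]))
        np.testing.assert_allclose(m1.coef_, m2.coef_, atol=1e-8)

    def test_strong_signal_test_cindex(self):
        beta = np.zeros(5)
        beta[:2] = [1.5, -1.5]
        train = simulate_cohort([400], beta, censor_rate=0.2, seed=31)
        test = simulate_cohort([300], beta, censor_rate=0.2, seed=32)
        for name in MODEL_REGISTRY:
            m = make_model(name)
            m.fit(train.features, (train.time, train.event))
            c = harrell_cindex(m.predict(test.features), test.time, test.event)
            floor = 0.6 if name == "stree" else 0.7
            assert c > floor, f"{name}: {c:.3f}"


class TestTune:
    def test_coxph_returns_empty_without_cv(self, small_cohort):
        X, y = small_cohort
        assert tune("coxph", X, y) == {}

    def test_grid_of_one_returned(self, small_cohort):
        X, y = small_cohort
        out = tune("stree", X, y, grid=[{"depth": 3}], seed=1)
        assert out == {"depth": 3}
        assert len(tune.last_log) == 1
        assert np.isfinite(tune.last_log[0]["cv_cindex"])

    def test_tuned_glmnet_beats_null(self):
        beta = np.zeros(8)
        beta[:2] = [1.5, -1.2]
        co = simulate_cohort([300], beta, censor_rate=0.2, seed=17)
        X, y = co.features, (co.time, co.event)
        params = tune("glmnet", X, y, seed=2,
                      grid=[{"alpha": a, "lam_frac": f}
                            for a in (1.0, 0.5) for f in (0.3, 0.6)])
        best = max(tune.last_log, key=lambda r: r["cv_cindex"])
        assert best["cv_cindex"] >= 0.6
        assert set(params) == {"alpha", "lam_frac"}

    def test_default_grids_nonempty(self):
        for name in MODEL_REGISTRY:
            grid = default_grid(name, 10)
            if name == "coxph":
                assert grid == []
            else:
                assert len(grid) >= 3
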