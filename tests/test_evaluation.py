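"""C-index, normalization transfer, LOCO CV, bootstrap, KM, Friedman/Nemenyi."""

import numpy as np
import pandas as pd
import pytest

from dosiofuse.evaluation import (
    CLINICAL_FIELDS, STRATEGIES, bootstrap_eval, build_strategy_table,
    encode_clinical, friedman_nemenyi, km_stratify, loco_cv,
    normalize_transfer,
)
from dosiofuse.metrics import harrell_cindex
from dosiofuse.models import fit_coxph
from dosiofuse.phantom import simulate_cohort


class TestHarrellCindex:
    def test_perfect_concordance(self):
        assert harrell_cindex([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_perfect_anticoncordance(self):
        assert harrell_cindex([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0

    def test_censored_pair_by_hand(self):
        # only pair (i=0 fails at t=1, j=1 censored later) is comparable
        assert harrell_cindex([2, 1], [1, 2], [1, 0]) == 1.0

    def test_tied_risks_count_half(self):
        assert harrell_cindex([1, 1], [1, 2], [1, 1]) == 0.5

    def test_complementarity_under_negation(self, rng):
        risk = rng.normal(size=50)
        time = rng.exponential(10, 50) + 0.01
        event = rng.integers(0, 2, 50)
        event[0] = 1
        c1 = harrell_cindex(risk, time, event)
        c2 = harrell_cindex(-risk, time, event)
        assert c1 + c2 == pytest.approx(1.0)

    def test_matches_scikit_survival(self, rng):
        from sksurv.metrics import concordance_index_censored

        risk = rng.normal(size=80)
        time = rng.exponential(100, 80) + 0.1
        event = rng.integers(0, 2, 80).astype(bool)
        event[:2] = True
        ours = harrell_cindex(risk, time, event.astype(int))
        ref = concordance_index_censored(event, time, risk)[0]
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_cindex([1, 2], [5, 5], [1, 1])  # ties in time, no earlier event


class TestNormalizeTransfer:
    def test_test_row_at_training_mean_is_zero(self, rng):
        train = pd.DataFrame(rng.normal(5, 2, size=(50, 3)), columns=list("abc"))
        test = pd.DataFrame([train.mean()], columns=list("abc"))
        _, test_z = normalize_transfer(train, test)
        np.testing.assert_allclose(test_z.to_numpy(), 0.0, atol=1e-12)

    def test_constant_training_column_zeroed(self, rng):
        train = pd.DataFrame({"a": np.ones(20), "b": rng.normal(size=20)})
        test = pd.DataFrame({"a": [5.0], "b": [0.3]})
        train_z, test_z = normalize_transfer(train, test)
        assert (train_z["a"] == 0).all() and (test_z["a"] == 0).all()

    def test_double_application_algebra(self, rng):
        # after one transfer the training table has mean 0 / sd 1 exactly,
        # so a second application is the identity map on both tables —
        # and a single application is NOT (value check)
        train = pd.DataFrame(rng.normal(5, 2, size=(50, 2)), columns=list("ab"))
        test = pd.DataFrame(rng.normal(5, 2, size=(10, 2)), columns=list("ab"))
        tr1, te1 = normalize_transfer(train, test)
        assert not np.allclose(te1.to_numpy(), test.to_numpy())
        tr2, te2 = normalize_transfer(tr1, te1)
        np.testing.assert_allclose(te2.to_numpy(), te1.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(tr2.to_numpy(), tr1.to_numpy(), atol=1e-12)

    def test_training_stats_only(self, rng):
        train = pd.DataFrame(rng.normal(0, 1, size=(50, 2)), columns=list("ab"))
        test_a = pd.DataFrame(rng.normal(10, 5, size=(10, 2)), columns=list("ab"))
        test_b = test_a + 100.0
        _, za = normalize_transfer(train, test_a)
        _, zb = normalize_transfer(train, test_b)
        # shifting the test set must shift its z-scores, not re-fit them
        assert not np.allclose(za.to_numpy(), zb.to_numpy())


class TestBootstrapEval:
    def _model_and_data(self):
        co = simulate_cohort([120], np.array([1.5, -1.0]), censor_rate=0.2, seed=14)
        model = fit_coxph(co.features, (co.time, co.event))
        return model, co

    def test_perfectly_concordant_mean_one_sd_zero(self):
        co = simulate_cohort([40], np.array([1.0]), censor_rate=0.0, seed=1)

        class Oracle:
            def predict(self, X):
                return -co.time  # shorter survival = higher risk, exactly

        mean, sd, dist = bootstrap_eval(Oracle(), co.features,
                                        (co.time, co.event), n_boot=50, seed=0)
        assert mean == 1.0 and sd == 0.0

    def test_single_replicate_boundary(self):
        model, co = self._model_and_data()
        _, _, dist = bootstrap_eval(model, co.features, (co.time, co.event),
                                    n_boot=1, seed=3)
        assert len(dist) == 1

    def test_mean_converges_to_point_estimate(self):
        model, co = self._model_and_data()
        point = harrell_cindex(model.predict(co.features), co.time, co.event)
        mean, _, _ = bootstrap_eval(model, co.features, (co.time, co.event),
                                    n_boot=2000, seed=5)
        assert abs(mean - point) < 0.01

    def test_sd_shrinks_with_test_size(self):
        sds = []
        for n in (80, 320):
            co = simulate_cohort([n], np.zeros(2), censor_rate=0.2, seed=9)
            model = fit_coxph(co.features, (co.time, co.event))
            _, sd, _ = bootstrap_eval(model, co.features, (co.time, co.event),
                                      n_boot=400, seed=9)
            sds.append(sd)
        # quadrupling n should roughly halve the bootstrap sd
        assert sds[1] < sds[0] * 0.75


class TestKMStratify:
    def test_identical_groups_p_near_one(self):
        time = np.tile([5.0, 10.0, 15.0, 20.0], 2)
        event = np.ones(8, int)
        risk = np.repeat([0.0, 1.0], 4)  # split groups share outcomes exactly
        _, p, _ = km_stratify(risk, (time, event))
        assert p > 0.9

    def test_hand_computed_logrank(self):
        # 6 subjects; statistic worked through the O-E/variance table by hand
        time = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        risk = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])  # group by median split
        from lifelines.statistics import logrank_test

        lr = logrank_test(time[:3], time[3:], event[:3], event[3:])
        assert lr.test_statistic == pytest.approx(0.0739030023094688, abs=1e-6)
        _, p, curves = km_stratify(risk, (time, event))
        assert p == pytest.approx(0.785736537959913, abs=1e-6)
        assert set(curves) == {"high", "low"}

    def test_strong_signal_separates_groups(self):
        co = simulate_cohort([400], np.array([1.5, -1.2]), censor_rate=0.25,
                             seed=19)
        _, p, _ = km_stratify(co.linear_predictor, (co.time, co.event))
        assert p < 0.05

    def test_massive_ties_rejected(self):
        time = np.arange(1.0, 9.0)
        event = np.ones(8, int)
        with pytest.raises(ValueError, match="cutoff"):
            km_stratify(np.ones(8), (time, event))


class TestFriedmanNemenyi:
    def test_identical_columns_statistic_zero(self, rng):
        col = rng.normal(size=12)
        with np.errstate(all="ignore"):
            p, pairwise = friedman_nemenyi(pd.DataFrame({
                "a": col, "b": col.copy(), "c": col.copy()}))
        assert p > 0.5
        assert pairwise.isna().all().all()

    def test_hand_table_statistic(self):
        # ranks per row: [1,2,3],[2,3,1],[1,3,2],[2,1,3] -> R = (6, 9, 9)
        # 12/(nk(k+1)) * sum(R^2) - 3n(k+1) = 12/48*198 - 48 = 1.5
        table = pd.DataFrame([
            [0.1, 0.2, 0.3], [0.2, 0.3, 0.1], [0.1, 0.3, 0.2], [0.2, 0.1, 0.3],
        ])
        from scipy.stats import chi2, friedmanchisquare

        stat, _ = friedmanchisquare(*[table[c] for c in table])
        assert stat == pytest.approx(1.5, abs=1e-6)
        p, _ = friedman_nemenyi(table)
        assert p == pytest.approx(float(chi2.sf(1.5, 2)), abs=1e-6)

    def test_dominating_strategy_detected(self, rng):
        base = rng.normal(0.65, 0.04, size=(30, 3))
        base[:, 0] += 0.1
        df = pd.DataFrame(base, columns=["winner", "s2", "s3"])
        p, pairwise = friedman_nemenyi(df)
        assert p < 0.05
        assert pairwise.loc["winner", "s2"] < 0.05
        assert pairwise.loc["winner", "s3"] < 0.05


class TestClinicalEncoding:
    def _records(self):
        return pd.DataFrame({
            "age": [55.0, 72.0], "sex": ["M", "F"],
            "site": ["Larynx", "Oropharynx"], "t_stage": ["T2", "T4"],
            "n_stage": ["N1", "N2b"], "tnm_stage": ["II", "IVA"],
            "treatment": ["CHRT", "Radiation"],
        })

    def test_exactly_seven_columns(self):
        enc = encode_clinical(self._records())
        assert enc.shape[1] == 7
        assert list(enc.columns) == CLINICAL_FIELDS

    def test_age_only_difference(self):
        rec = self._records()
        rec.loc[1] = rec.loc[0]
        rec.loc[1, "age"] = 80.0
        enc = encode_clinical(rec)
        diff = (enc.loc[0] != enc.loc[1])
        assert diff.sum() == 1 and diff["age"]

    def test_t_stage_ordinal(self):
        rec = pd.concat([self._records().iloc[[0]]] * 4, ignore_index=True)
        rec["t_stage"] = ["T1", "T2", "T3", "T4"]
        enc = encode_clinical(rec)
        assert enc["t_stage"].is_monotonic_increasing

    def test_unknown_category_lists_dictionary(self):
        rec = self._records()
        rec.loc[0, "site"] = "Mars"
        with pytest.raises(ValueError, match="Oropharynx"):
            encode_clinical(rec)


class TestStrategyTables:
    def test_column_counts(self, rng):
        feats = pd.DataFrame(rng.random((6, 215)),
                             columns=[f"f{i:03d}" for i in range(215)])
        clin = pd.DataFrame(rng.random((6, 7)), columns=CLINICAL_FIELDS)
        modal = {k: feats for k in ("ct", "dose", "llrr", "wavelet", "wls")}
        assert build_strategy_table(modal, clin, "Clinical").shape[1] == 7
        for strat in ("CT", "Dose", "LLRR", "Wavelet", "WLS"):
            assert build_strategy_table(modal, clin, strat).shape[1] == 222
        assert build_strategy_table(modal, clin, "DualCTDose").shape[1] == 437

    def test_missing_modality_patient_dropped(self, rng):
        feats = pd.DataFrame(rng.random((5, 215)),
                             columns=[f"f{i:03d}" for i in range(215)])
        clin = pd.DataFrame(rng.random((6, 7)), columns=CLINICAL_FIELDS)
        out = build_strategy_table({"ct": feats}, clin, "CT")
        assert len(out) == 5
        assert out.attrs["dropped_patients"] == [5]

    def test_grid_dimensions(self):
        from dosiofuse.models import MODEL_REGISTRY
        from dosiofuse.selection import SELECTOR_REGISTRY

        assert len(STRATEGIES) == 7
        assert len(SELECTOR_REGISTRY) * len(MODEL_REGISTRY) == 30


class TestLocoCV:
    def test_fold_count_equals_centers(self):
        co = simulate_cohort([60, 60, 60], np.array([1.2, -1.0, 0.0, 0.0]),
                             censor_rate=0.2, seed=25)
        res = loco_cv(co.features, (co.time, co.event), co.center,
                      "mi", "coxph", n_boot=100, seed=1)
        assert len(res.folds) == 3
        assert {f.center for f in res.folds} == {"C1", "C2", "C3"}

    def test_exchangeable_centers_similar_scores(self):
        co = simulate_cohort([400, 400], np.array([1.5, -1.2, 0.0, 0.0]),
                             censor_rate=0.2, seed=26)
        res = loco_cv(co.features, (co.time, co.event), co.center,
                      "mi", "coxph", n_boot=200, seed=2)
        scores = [f.cindex_mean for f in res.folds]
        assert abs(scores[0] - scores[1]) < 0.05

    def test_no_leakage_from_test_center(self):
        co = simulate_cohort([80, 80, 80], np.array([1.2, -1.0, 0.0, 0.0]),
                             censor_rate=0.2, seed=27)
        res1 = loco_cv(co.features, (co.time, co.event), co.center,
                       "mi", "coxph", n_boot=50, seed=3)
        # poison the held-out center C1: outcomes shuffled, features shifted
        rng = np.random.default_rng(0)
        te = co.center == "C1"
        time2, event2 = co.time.copy(), co.event.copy()
        idx = np.nonzero(te)[0]
        perm = rng.permutation(idx)
        time2[idx], event2[idx] = co.time[perm], co.event[perm]
        X2 = co.features.copy()
        X2.loc[te] = X2.loc[te].to_numpy() * 3.0 + 7.0
        res2 = loco_cv(X2, (time2, event2), co.center,
                       "mi", "coxph", n_boot=50, seed=3)
        f1 = next(f for f in res1.folds if f.center == "C1")
        f2 = next(f for f in res2.folds if f.center == "C1")
        assert f1.selected_features == f2.selected_features
        np.testing.assert_allclose(
            [f1.coef[k] for k in f1.selected_features],
            [f2.coef[k] for k in f2.selected_features], atol=1e-10)
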