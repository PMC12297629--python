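"""Model training, AUC/DeLong/Brier, exact Shapley, and decision curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stilmap.models import (
    FEATURES_M1,
    FEATURES_M2,
    PatientRecord,
    brier_score,
    decision_curve,
    delong_test,
    exact_shapley,
    roc_auc,
    split_cohort,
    summarize_cohorts,
    train_model,
)

from oracles import auc_by_pair_counting, net_benefit_by_counting

SMALL_GRID = {"n_estimators": (100,), "max_depth": (3,), "min_samples_leaf": (1, 5)}


def synthetic_cohort(n=100, seed=0, beta_til=-3.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "age_cat": rng.choice(3, n, p=[0.05, 0.47, 0.48]),
            "t_stage": rng.choice(4, n, p=[0.35, 0.45, 0.13, 0.07]),
            "til_score": rng.beta(2, 5, n),
            "stilc": rng.choice([1, 2], n),
        }
    )
    lp = -1 + 0.6 * df.t_stage + 0.1 * df.age_cat + beta_til * df.til_score \
        + 0.7 * (df.stilc == 1)
    df["lnm"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return df


class TestPatientRecord:
    def test_valid_record_accepted(self):
        PatientRecord("P1", age_cat=1, t_stage=2, til_score=0.3, stilc=2, lnm=0)

    @pytest.mark.parametrize("field,value", [
        ("age_cat", 3), ("t_stage", 4), ("til_score", 1.2), ("stilc", 0),
        ("lnm", 2),
    ])
    def test_out_of_coding_values_rejected(self, field, value):
        kwargs = dict(patient_id="P", age_cat=0, t_stage=0, til_score=0.5,
                      stilc=1, lnm=0)
        kwargs[field] = value
        with pytest.raises(ValueError):
            PatientRecord(**kwargs)


class TestSplit:
    def test_stratified_8_to_2(self):
        df = synthetic_cohort(100, seed=1)
        df["lnm"] = np.array([1] * 30 + [0] * 70)
        train, val = split_cohort(df, seed=0)
        assert len(train) == 80 and len(val) == 20
        assert train.lnm.sum() == 24 and val.lnm.sum() == 6
        assert set(train.patient_id) | set(val.patient_id) == set(df.patient_id)
        assert set(train.patient_id) & set(val.patient_id) == set()

    def test_same_seed_reproduces_split(self):
        df = synthetic_cohort(60, seed=2)
        a = split_cohort(df, seed=5)[0]
        b = split_cohort(df, seed=5)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self):
        df = synthetic_cohort(40, seed=3)
        df["lnm"] = 0
        with pytest.raises(ValueError, match="single-class"):
            split_cohort(df)

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(synthetic_cohort(40), test_size=0.0)


class TestTrainModel:
    def test_separable_outcome_gives_training_auc_one(self):
        df = synthetic_cohort(80, seed=4)
        df["lnm"] = (df.t_stage >= 2).astype(int)
        model = train_model(df, FEATURES_M2, seed=0, param_grid=SMALL_GRID)
        assert roc_auc(model.predict_proba(df), df.lnm.to_numpy()) == 1.0

    def test_permuted_outcome_cv_auc_in_null_band(self):
        aucs = []
        for seed in range(10):
            df = synthetic_cohort(100, seed=seed)
            rng = np.random.default_rng(seed)
            df["lnm"] = rng.permutation(df["lnm"].to_numpy())
            if df.lnm.nunique() < 2:
                continue
            model = train_model(df, FEATURES_M1, seed=seed,
                                param_grid=SMALL_GRID)
            aucs.append(model.cv_auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_m2_ignores_til_score_by_construction(self):
        df = synthetic_cohort(80, seed=5)
        m2 = train_model(df, FEATURES_M2, seed=0, param_grid=SMALL_GRID)
        shifted = df.copy()
        shifted["til_score"] = 1.0 - shifted["til_score"]
        np.testing.assert_array_equal(m2.predict_proba(df),
                                      m2.predict_proba(shifted))

    def test_missing_feature_column_rejected(self):
        df = synthetic_cohort(40, seed=6).drop(columns=["stilc"])
        with pytest.raises(ValueError, match="stilc"):
            train_model(df, FEATURES_M1, seed=0, param_grid=SMALL_GRID)

    def test_deterministic_per_seed(self):
        df = synthetic_cohort(60, seed=7)
        a = train_model(df, FEATURES_M1, seed=9, param_grid=SMALL_GRID)
        b = train_model(df, FEATURES_M1, seed=9, param_grid=SMALL_GRID)
        assert a.best_params == b.best_params
        np.testing.assert_array_equal(a.predict_proba(df), b.predict_proba(df))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_four_record_example_matches_pair_counting(self):
        probs = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert roc_auc(probs, labels) == pytest.approx(
            auc_by_pair_counting(probs, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_bruteforce_concordance_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        probs = rng.choice([0.1, 0.25, 0.5, 0.5, 0.9], size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(probs, labels) == pytest.approx(
            auc_by_pair_counting(probs, labels), abs=1e-12)


class TestDeLong:
    def test_identical_scores_z_zero_p_one(self):
        p = np.array([0.2, 0.8, 0.3, 0.9, 0.5, 0.1])
        y = np.array([0, 1, 0, 1, 1, 0])
        z, pv = delong_test(p, p, y)
        assert z == 0.0 and pv == 1.0

    def test_antisymmetric_in_model_order(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 60)
        y[:5] = 1
        y[5:10] = 0
        pa = np.clip(0.5 * y + rng.normal(0, 0.3, 60), 0, 1)
        pb = rng.random(60)
        z1, p1 = delong_test(pa, pb, y)
        z2, p2 = delong_test(pb, pa, y)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert z1 != 0.0

    def test_variance_close_to_paired_bootstrap(self):
        # structural-components variance vs a 2000-replicate paired bootstrap
        # of dAUC on a fixed n=100 cohort
        rng = np.random.default_rng(12)
        n = 100
        y = np.array([1] * 40 + [0] * 60)
        pa = np.clip(0.55 * y + rng.normal(0.2, 0.25, n), 0, 1)
        pb = np.clip(0.25 * y + rng.normal(0.35, 0.3, n), 0, 1)
        z, _ = delong_test(pa, pb, y)
        dauc = roc_auc(pa, y) - roc_auc(pb, y)
        var_delong = (dauc / z) ** 2

        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            boots.append(roc_auc(pa[idx], yb) - roc_auc(pb[idx], yb))
        var_boot = np.var(boots, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.15)


class TestBrier:
    def test_perfect_probabilities_score_zero(self):
        assert brier_score([0.0, 1.0], [0, 1]) == 0.0

    def test_constant_half_scores_quarter(self):
        assert brier_score([0.5] * 8, [0, 1] * 4) == 0.25

    def test_two_record_arithmetic(self):
        assert brier_score([0.8, 0.4], [1, 0]) == pytest.approx(0.10)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            brier_score([1.2, 0.4], [1, 0])


class TestExactShapley:
    def _additive_predict(self, X):
        # f = g(t_stage) + h(til_score), independent of the other features
        return 0.05 + 0.1 * X[:, 1] - 0.3 * X[:, 2]

    def test_additive_model_matches_closed_form(self):
        df = synthetic_cohort(30, seed=8)
        bg = synthetic_cohort(50, seed=9)
        phi = exact_shapley(self._additive_predict, df, bg,
                            features=FEATURES_M1)
        X = df[list(FEATURES_M1)].to_numpy(float)
        B = bg[list(FEATURES_M1)].to_numpy(float)
        # for an additive f, the interventional Shapley value of feature j is
        # f_j(x_j) - mean_b f_j(b_j)
        np.testing.assert_allclose(
            phi[:, 1], 0.1 * X[:, 1] - 0.1 * B[:, 1].mean(), atol=1e-9)
        np.testing.assert_allclose(
            phi[:, 2], -0.3 * X[:, 2] + 0.3 * B[:, 2].mean(), atol=1e-9)

    def test_dummy_features_get_zero_attribution(self):
        df = synthetic_cohort(20, seed=10)
        bg = synthetic_cohort(30, seed=11)
        phi = exact_shapley(self._additive_predict, df, bg,
                            features=FEATURES_M1)
        np.testing.assert_allclose(phi[:, 0], 0.0, atol=1e-9)  # age unused
        np.testing.assert_allclose(phi[:, 3], 0.0, atol=1e-9)  # stilc unused

    def test_efficiency_axiom_on_fitted_forest(self):
        df = synthetic_cohort(60, seed=12)
        model = train_model(df, FEATURES_M1, seed=0, param_grid=SMALL_GRID)
        sub, bg = df.iloc[:15], df.iloc[15:45]
        phi = exact_shapley(model, sub, bg)
        expected = model.predict_proba(sub) - model.predict_proba(bg).mean()
        np.testing.assert_allclose(phi.sum(axis=1), expected, atol=1e-9)

    def test_symmetry_axiom(self):
        # two features entering f identically get identical attributions
        # whenever their values coincide
        def f(X):
            return X[:, 0] + X[:, 1]

        X = np.array([[2.0, 2.0], [1.0, 1.0], [3.0, 3.0]])
        B = np.array([[0.0, 4.0], [4.0, 0.0]])
        phi = exact_shapley(f, X, B, features=("u", "v"))
        np.testing.assert_allclose(phi[:, 0], phi[:, 1], atol=1e-9)

    def test_empty_background_rejected(self):
        df = synthetic_cohort(20, seed=13)
        with pytest.raises(ValueError, match="background"):
            exact_shapley(self._additive_predict, df, df.iloc[:0],
                          features=FEATURES_M1)


class TestDecisionCurve:
    def test_treat_all_matches_closed_form_everywhere(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        y[0], y[1] = 0, 1
        p = rng.random(200)
        dca = decision_curve(p, y)
        prev = y.mean()
        expected = prev - (1 - prev) * dca.threshold / (1 - dca.threshold)
        np.testing.assert_allclose(dca.nb_all, expected, atol=1e-12)

    def test_perfect_probabilities_flat_at_prevalence(self):
        y = np.array([1, 0, 1, 0, 0])
        dca = decision_curve(y.astype(float), y)
        np.testing.assert_allclose(dca.nb_model, y.mean(), atol=1e-12)

    def test_treat_none_is_identically_zero(self):
        y = np.array([1, 0, 1, 0])
        dca = decision_curve([0.9, 0.1, 0.7, 0.2], y)
        assert (dca.nb_none == 0).all()

    def test_ten_record_cohort_matches_hand_counting(self):
        probs = [0.9, 0.8, 0.7, 0.6, 0.55, 0.45, 0.4, 0.3, 0.2, 0.1]
        labels = [1, 1, 0, 1, 0, 1, 0, 0, 0, 0]
        dca = decision_curve(probs, labels, thresholds=np.array([0.5]))
        assert dca.nb_model[0] == pytest.approx(
            net_benefit_by_counting(probs, labels, 0.5), abs=1e-12)
        # at t=0.5: treated = first 5 -> TP=3, FP=2 -> 0.3 - 0.2*1 = 0.1
        assert dca.nb_model[0] == pytest.approx(0.1, abs=1e-12)

    def test_threshold_one_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5, 0.6], [0, 1], thresholds=np.array([0.5, 1.0]))


class TestCohortSummary:
    def test_identical_groups_give_null_chi_square(self):
        df = synthetic_cohort(50, seed=14)
        out = summarize_cohorts({"a": df, "b": df.copy()})
        chi = out[(out.test == "chi2")]
        assert np.allclose(chi.statistic, 0.0)
        assert np.allclose(chi.p, 1.0)

    def test_two_by_two_table_matches_hand_formula(self):
        # groups (10,20) vs (20,10): chi2 = sum (O-E)^2/E = 6.6667
        da = pd.DataFrame({"lnm": [1] * 10 + [0] * 20})
        db_ = pd.DataFrame({"lnm": [1] * 20 + [0] * 10})
        out = summarize_cohorts({"a": da, "b": db_})
        chi = out[(out.variable == "lnm") & (out.test == "chi2")]
        o = np.array([[10, 20], [20, 10]])
        e = np.outer(o.sum(1), o.sum(0)) / o.sum()
        assert chi.statistic.iloc[0] == pytest.approx(((o - e) ** 2 / e).sum())

    def test_til_score_against_itself_p_one(self):
        df = synthetic_cohort(40, seed=15)
        out = summarize_cohorts({"a": df, "b": df.copy()})
        t = out[out.test == "welch_t"]
        assert t.p.iloc[0] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        df = synthetic_cohort(30, seed=16)
        with pytest.raises(ValueError, match="empty"):
            summarize_cohorts({"a": df, "b": df.iloc[:0]})
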