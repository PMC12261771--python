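"""Selection, splitting, the model bench, evaluation, importance and
the logistic confirmation step."""

import numpy as np
import pandas as pd
import pytest

from preshock.modeling import (ModelingError, build_weighted_ensemble,
                               evaluate, fit_models, importance_report,
                               logistic_confirmation, mutual_information_rank,
                               patient_split, permutation_importance_auc,
                               select_top_k, shap_values)


def _table(n=400, p=6, informative=0, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x = rng.standard_normal((n, p))
    if informative:
        x[:, :informative] += (2 * y[:, None] - 1) * (1.5 - noise)
    cols = [f"f{i}" for i in range(p)]
    return pd.DataFrame(x, columns=cols), y


class TestMutualInformation:
    def test_perfectly_dependent_feature_approaches_ln2(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 2000)
        df = pd.DataFrame({"dup": y.astype(float),
                           "noise": rng.standard_normal(2000)})
        ranking = dict(mutual_information_rank(df, y, seed=1))
        assert ranking["dup"] == pytest.approx(np.log(2), abs=0.05)
        assert ranking["noise"] < 0.05

    def test_independent_feature_below_permutation_null(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 500)
        x = rng.standard_normal(500)
        mi = dict(mutual_information_rank(pd.DataFrame({"x": x}), y, seed=2))["x"]
        null = []
        for k in range(40):
            mi_p = mutual_information_rank(
                pd.DataFrame({"x": x}), rng.permutation(y), seed=2)
            null.append(mi_p[0][1])
        assert mi <= np.percentile(null, 95) + 1e-9

    def test_duplicated_columns_get_identical_mi_and_stable_order(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 300)
        x = rng.standard_normal(300) + y
        df = pd.DataFrame({"a": x, "b": x.copy()})
        ranking = mutual_information_rank(df, y, seed=3)
        assert ranking[0][1] == ranking[1][1]
        assert [n for n, _ in ranking] == ["a", "b"]  # tie -> column order

    def test_constant_label_raises(self):
        df, _ = _table(50)
        with pytest.raises(ModelingError):
            mutual_information_rank(df, np.zeros(50), seed=0)


class TestSelectTopK:
    RANKING = [(f"f{i}", 1.0 / (i + 1)) for i in range(299)]

    def test_default_returns_65(self):
        assert len(select_top_k(self.RANKING)) == 65

    def test_k_equal_total_is_identity(self):
        assert select_top_k(self.RANKING, 299) == [n for n, _ in self.RANKING]

    def test_out_of_range_raises(self):
        with pytest.raises(ModelingError):
            select_top_k(self.RANKING, 300)


class TestPatientSplit:
    def test_100_patients_split_60_20_20(self):
        pats = [f"p{i}" for i in range(100)]
        split = patient_split(pats, seed=0)
        assert len(split.patients("train")) == 60
        assert len(split.patients("validation")) == 20
        assert len(split.patients("test")) == 20

    def test_disjoint_and_exhaustive(self):
        pats = [f"p{i}" for i in range(47)]
        split = patient_split(pats, seed=1)
        parts = [set(split.patients(p)) for p in ("train", "validation", "test")]
        assert parts[0] | parts[1] | parts[2] == set(pats)
        assert not (parts[0] & parts[1]) and not (parts[0] & parts[2])
        assert not (parts[1] & parts[2])

    def test_same_seed_identical_different_seed_not(self):
        pats = [f"p{i}" for i in range(40)]
        assert patient_split(pats, seed=5).assignment == patient_split(pats, seed=5).assignment
        assert patient_split(pats, seed=5).assignment != patient_split(pats, seed=6).assignment

    def test_too_few_patients_raises(self):
        with pytest.raises(ModelingError):
            patient_split(["a", "b"], seed=0)


class TestModelBench:
    def test_separable_data_trains_to_high_auc(self):
        x, y = _table(300, informative=3, seed=3)
        models = fit_models(x, y, seed=0)
        assert set(models) == {"XGBoost", "LightGBM", "HistGB", "RF", "ET"}
        from sklearn.metrics import roc_auc_score
        for m in models.values():
            assert roc_auc_score(y, m.predict_proba(x)[:, 1]) >= 0.99

    def test_permuted_labels_give_chance_validation_auc(self):
        x, y = _table(2000, informative=3, seed=4)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        xt, yt = x.iloc[:1200], y_perm[:1200]
        xv, yv = x.iloc[1200:], y_perm[1200:]
        models = fit_models(xt, yt, seed=0)
        from sklearn.metrics import roc_auc_score
        for m in models.values():
            assert 0.4 <= roc_auc_score(yv, m.predict_proba(xv)[:, 1]) <= 0.6

    def test_single_class_training_raises(self):
        x, _ = _table(50)
        with pytest.raises(ModelingError):
            fit_models(x, np.ones(50), seed=0)

    def test_same_seed_identical_predictions(self):
        x, y = _table(200, informative=2, seed=5)
        a = fit_models(x, y, seed=7)
        b = fit_models(x, y, seed=7)
        for name in a:
            np.testing.assert_array_equal(a[name].predict_proba(x),
                                          b[name].predict_proba(x))


class TestWeightedEnsemble:
    def test_dominant_model_gets_largest_weight_and_auc_guarantee(self):
        x, y = _table(400, informative=2, seed=6)
        xv, yv = _table(400, informative=2, seed=7)
        models = fit_models(x, y, seed=0)
        ens = build_weighted_ensemble(models, xv, yv)
        assert sum(ens.weights.values()) == pytest.approx(1.0)
        assert all(w >= 0 for w in ens.weights.values())
        from sklearn.metrics import roc_auc_score
        best_single = max(roc_auc_score(yv, m.predict_proba(xv)[:, 1])
                          for m in models.values())
        ens_auc = roc_auc_score(yv, ens.predict_proba(xv)[:, 1])
        assert ens_auc >= best_single - 1e-9

    def test_identical_base_models_give_identical_predictions(self):
        x, y = _table(200, informative=2, seed=8)
        m = fit_models(x, y, seed=0)["RF"]
        ens = build_weighted_ensemble({"a": m, "b": m}, x, y)
        np.testing.assert_allclose(ens.predict_proba(x)[:, 1],
                                   m.predict_proba(x)[:, 1], atol=1e-12)


class _FixedModel:
    def __init__(self, prob):
        self.prob = np.asarray(prob, float)

    def predict_proba(self, x):
        return np.column_stack([1 - self.prob, self.prob])


class TestEvaluate:
    def test_perfect_predictor(self):
        y = np.array([0, 1] * 20)
        rep = evaluate(_FixedModel(y.astype(float)), pd.DataFrame(np.zeros((40, 1))),
                       y, np.repeat([f"p{i}" for i in range(8)], 5),
                       "perfect", n_boot=50)
        assert rep.accuracy == 100.0 and rep.auc == 1.0
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0
        assert rep.confusion[0, 1] == 0 and rep.confusion[1, 0] == 0

    def test_all_positive_predictor(self):
        y = np.array([0, 1] * 20)
        rep = evaluate(_FixedModel(np.ones(40)), pd.DataFrame(np.zeros((40, 1))),
                       y, np.repeat([f"p{i}" for i in range(8)], 5),
                       n_boot=50)
        assert rep.sensitivity == 100.0 and rep.specificity == 0.0

    def test_coin_flip_near_chance(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 300)
        rep = evaluate(_FixedModel(rng.uniform(size=600)),
                       pd.DataFrame(np.zeros((600, 1))), y,
                       np.repeat([f"p{i}" for i in range(60)], 10), n_boot=50)
        assert 40 <= rep.accuracy <= 60
        assert 0.4 <= rep.auc <= 0.6

    def test_ci_brackets_point_estimate(self):
        x, y = _table(300, informative=1, seed=9, noise=1.0)
        models = fit_models(x.iloc[:200], y[:200], seed=0)
        rep = evaluate(models["RF"], x.iloc[200:], y[200:],
                       np.repeat([f"p{i}" for i in range(20)], 5), n_boot=200)
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]


class TestImportance:
    def test_single_feature_model_attributes_everything_to_it(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 400)
        x = pd.DataFrame({"signal": y + 0.1 * rng.standard_normal(400),
                          "flat1": np.zeros(400), "flat2": np.zeros(400)})
        models = fit_models(x, y, seed=0)
        imp = importance_report(models["XGBoost"], x, y)
        assert imp.iloc[0]["feature"] == "signal"
        total = imp["importance"].sum()
        assert imp.iloc[0]["importance"] >= 0.99 * total

    def test_tree_shap_additivity(self):
        import xgboost as xgb
        x, y = _table(300, informative=2, seed=11)
        model = fit_models(x, y, seed=0)["XGBoost"]
        contrib = model.get_booster().predict(xgb.DMatrix(x), pred_contribs=True)
        margin = model.get_booster().predict(xgb.DMatrix(x), output_margin=True)
        np.testing.assert_allclose(contrib.sum(axis=1), margin, atol=1e-4)

    def test_permuting_top_feature_hurts_more_than_bottom(self):
        x, y = _table(500, informative=1, seed=12)
        models = fit_models(x, y, seed=0)
        drops = permutation_importance_auc(models["RF"], x, y, seed=0)
        assert drops[0] > drops[-1]
        assert drops[0] > 0.05

    def test_ensemble_falls_back_to_permutation(self):
        x, y = _table(200, informative=1, seed=13)
        models = fit_models(x, y, seed=0)
        ens = build_weighted_ensemble(models, x, y)
        assert shap_values(ens, x) is None
        imp = importance_report(ens, x, y)
        assert (imp["method"] == "permutation_auc_drop").all()


class TestLogisticConfirmation:
    def test_two_by_two_cross_product_odds_ratio(self):
        # counts [[40, 10], [10, 40]] -> OR = 16
        feat = np.array([0] * 50 + [1] * 50, dtype=float)
        y = np.array([0] * 40 + [1] * 10 + [0] * 10 + [1] * 40)
        out = logistic_confirmation(pd.DataFrame({"f": feat}), y, None)
        row = out[(out.feature == "f") & (out.model == "unadjusted")].iloc[0]
        assert row["or"] == pytest.approx(16.0, abs=1e-4)
        assert row["converged"]
        assert row["p"] < 0.01 and row["stars"] == "**"

    def test_scaling_feature_scales_log_or(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(400)
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-x))).astype(int)
        out1 = logistic_confirmation(pd.DataFrame({"f": x}), y, None)
        out2 = logistic_confirmation(pd.DataFrame({"f": 10 * x}), y, None)
        c1 = out1.iloc[0]["coef"]
        c2 = out2.iloc[0]["coef"]
        assert c2 == pytest.approx(c1 / 10, rel=1e-4)

    def test_independent_feature_ci_contains_one(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(500)
        y = rng.integers(0, 2, 500)
        out = logistic_confirmation(pd.DataFrame({"f": x}), y, None)
        row = out.iloc[0]
        assert row["or_lo"] <= 1.0 <= row["or_hi"]

    def test_adjusted_model_emitted_with_covariates(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(200)
        y = (x + 0.5 * rng.standard_normal(200) > 0).astype(int)
        covs = pd.DataFrame({"age": rng.normal(65, 10, 200),
                             "sex": rng.integers(0, 2, 200),
                             "bmi": rng.normal(28, 5, 200),
                             "neck_cm": rng.normal(38, 3, 200),
                             "waist_cm": rng.normal(100, 10, 200)})
        out = logistic_confirmation(pd.DataFrame({"f": x}), y, covs)
        assert set(out["model"]) == {"unadjusted", "adjusted"}

    def test_separation_reported_not_dropped(self):
        feat = np.linspace(-2, 2, 60)
        y = (feat > 0).astype(int)
        out = logistic_confirmation(pd.DataFrame({"f": feat}), y, None)
        row = out.iloc[0]
        assert np.isfinite(row["coef"]) and row["coef"] > 0
        assert not row["converged"]


class TestSweepTopK:
    def test_sweep_reports_validation_auc_per_k_and_picks_best(self):
        rng = np.random.default_rng(20)
        n = 300
        y = rng.integers(0, 2, n)
        x = pd.DataFrame(rng.standard_normal((n, 40)),
                         columns=[f"f{i}" for i in range(40)])
        x["f0"] += 2.0 * y
        patients = np.repeat([f"p{i}" for i in range(30)], 10)
        ranking = mutual_information_rank(x, y, seed=0)
        from preshock.modeling import sweep_top_k

        best_k, table = sweep_top_k(x, y, patients, ranking, ks=(5, 10, 20), seed=0)
        assert best_k in (5, 10, 20)
        assert list(table["k"]) == [5, 10, 20]
        assert table["val_auc"].between(0, 1).all()
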