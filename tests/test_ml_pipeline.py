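import datetime as dt

import numpy as np
import pandas as pd
import pytest

from oa_phenotyper.cohort_builder import DateInterval, STUDY_WINDOW
from oa_phenotyper.ml_pipeline import (
    FeatureMatrix,
    MLConfig,
    extract_features,
    fit_model,
    mean_abs_shap,
    nested_cv,
    predict_proba,
    rf_rfe,
    smote,
)
from oa_phenotyper.records_io import (
    CodeSystem,
    DrugClaim,
    DrugClass,
    GoldLabel,
    PatientDB,
    ProcedureEvent,
)

from conftest import dx, make_patient

D = dt.date
W = DateInterval(D(2018, 7, 1), D(2019, 12, 31))


def _tiny_db(code_sets):
    db = PatientDB()
    rec = make_patient(
        "pa", birth_year=1950,
        diagnoses=[dx("pa", D(2019, 1, 1)), dx("pa", D(2019, 2, 1))],
        drugs=[DrugClaim("pa", D(2019, 3, 1), DrugClass.OPIOID_SA, 30.0),
               DrugClaim("pa", D(2019, 5, 1), DrugClass.OPIOID_SA, 30.0)],
        procedures=[ProcedureEvent("pa", D(2019, 4, 1), "20610", CodeSystem.CPT4, 250.0)],
    )
    db.add(rec, GoldLabel("pa", True, True, True))
    db.add(make_patient("pb", birth_year=1960, diagnoses=[dx("pb", D(2019, 1, 1))]),
           GoldLabel("pb", True, False, False))
    db.add(make_patient("pc", birth_year=1970), GoldLabel("pc", False, False, False))
    return db


class TestExtractFeatures:
    def test_flags_counts_and_exclusion_of_non_oa(self, code_sets):
        db = _tiny_db(code_sets)
        windows = {pid: W for pid in db.records}
        fm = extract_features(db, windows, code_sets)
        # the non-OA patient is excluded from the learning cohort
        assert list(fm.X.index) == ["pa", "pb"]
        assert fm.X.loc["pa", "opioid_sa_flag"] == 1.0
        assert fm.X.loc["pa", "opioid_sa_count"] == 2.0
        assert fm.X.loc["pb", "opioid_sa_flag"] == 0.0
        assert fm.y.loc["pa"] and not fm.y.loc["pb"]

    def test_empty_patient_all_zero(self, code_sets):
        db = _tiny_db(code_sets)
        windows = {pid: W for pid in db.records}
        fm = extract_features(db, windows, code_sets)
        flags = [c for c in fm.X.columns if c.endswith("_flag")]
        row = fm.X.loc["pb"]
        assert row["daily_healthcare_cost"] == 0.0
        assert row[[f for f in flags if not f.startswith("oa_hip_knee")]].sum() == 0.0

    def test_feature_namespace(self, code_sets):
        db = _tiny_db(code_sets)
        fm = extract_features(db, {pid: W for pid in db.records}, code_sets)
        cols = set(fm.X.columns)
        assert "ia_corticosteroid_flag" in cols  # corticosteroid injection
        assert "daily_healthcare_cost" in cols
        assert "nerve_block_flag" in cols
        assert "age" in cols and "charlson_score" in cols
        # age anchored at the extraction-window start year
        assert fm.X.loc["pa", "age"] == W.start.year - 1950

    def test_deterministic(self, code_sets, synth_db, synth_windows):
        a = extract_features(synth_db, synth_windows, code_sets)
        b = extract_features(synth_db, synth_windows, code_sets)
        pd.testing.assert_frame_equal(a.X, b.X)


class TestSmote:
    def _imbalanced(self, seed=0, n_min=20, n_maj=60):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            np.vstack([rng.normal(0, 1, (n_maj, 3)), rng.normal(3, 1, (n_min, 3))]),
            columns=["a", "b", "c"],
        )
        y = pd.Series([False] * n_maj + [True] * n_min, name="case")
        return X, y

    def test_balanced_input_unchanged(self):
        X, y = self._imbalanced(n_min=30, n_maj=30)
        X2, y2, mask = smote(X, y, k=3, target_ratio=1.0, seed=1)
        pd.testing.assert_frame_equal(X, X2)
        assert not mask.any()

    def test_target_ratio_reached_and_originals_preserved(self):
        X, y = self._imbalanced()
        X2, y2, mask = smote(X, y, k=5, target_ratio=1.0, seed=1)
        assert y2.sum() == 60 and (~y2).sum() == 60
        pd.testing.assert_frame_equal(X2.iloc[: len(X)], X, check_index_type=False)
        assert mask.sum() == 40 and mask[: len(X)].sum() == 0

    def test_synthetic_points_are_convex_combinations(self):
        """With two minority points and k=1 every synthetic row lies on the
        segment between them."""
        X = pd.DataFrame(
            {"a": [5.0, 5.0, 5.0, 5.0, 0.0, 1.0], "b": [5.0, 6.0, 7.0, 8.0, 0.0, 1.0]}
        )
        y = pd.Series([False] * 4 + [True] * 2)
        X2, y2, mask = smote(X, y, k=1, target_ratio=1.0, seed=2)
        syn = X2[mask].to_numpy()
        for row in syn:
            t = row[0]  # segment: (t, t) for t in [0, 1]
            assert 0.0 <= t <= 1.0 and row[1] == pytest.approx(t)

    def test_minority_too_small_for_k(self):
        X, y = self._imbalanced(n_min=4)
        with pytest.raises(ValueError, match="reduce k"):
            smote(X, y, k=5)

    def test_reproducible(self):
        X, y = self._imbalanced()
        a = smote(X, y, seed=7)[0]
        b = smote(X, y, seed=7)[0]
        pd.testing.assert_frame_equal(a, b)


class TestRfRfe:
    def _planted(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 12)), columns=[f"f{i:02d}" for i in range(12)])
        signal = X["f01"] + X["f05"] - 2 * X["f09"]
        y = pd.Series(signal > 0, name="case")
        return X, y

    def test_identity_at_full_width(self):
        X, y = self._planted(0)
        assert set(rf_rfe(X, y, threshold=12, seed=0)) == set(X.columns)

    def test_selection_size_is_exact(self):
        X, y = self._planted(0)
        for t in (1, 3, 7, 11):
            assert len(rf_rfe(X, y, threshold=t, seed=0)) == t

    def test_planted_signal_recovered(self):
        """The three signal-bearing columns survive in >= 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            X, y = self._planted(seed)
            if set(rf_rfe(X, y, threshold=3, seed=seed)) == {"f01", "f05", "f09"}:
                hits += 1
        assert hits >= 9

    def test_threshold_validation(self):
        X, y = self._planted(0)
        with pytest.raises(ValueError):
            rf_rfe(X, y, threshold=0)
        with pytest.raises(ValueError):
            rf_rfe(X, y, threshold=13)


class TestFitModel:
    def test_logistic_monotone_in_single_feature(self):
        X = pd.DataFrame({"x": np.linspace(-3, 3, 40)})
        y = pd.Series(X["x"].to_numpy() > 0)
        model = fit_model(X, y, "logistic", {"C": 1.0}, seed=0)
        scores = predict_proba(model, X)
        assert np.all(np.diff(scores) >= 0)

    def test_cart_recovers_split_point(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 300)
        X = pd.DataFrame({"x": x})
        y = pd.Series(x > 6.2)
        model = fit_model(X, y, "cart", {"max_depth": 1}, seed=0)
        # exhaustive oracle: scan every midpoint between sorted unique values
        # for the split minimizing misclassification
        xs = np.sort(np.unique(x))
        mids = (xs[:-1] + xs[1:]) / 2
        errors = np.array([np.sum((x > m) != y.to_numpy()) for m in mids])
        oracle_thr = mids[int(np.argmin(errors))]
        thr = model.tree_.threshold[0]
        # both land in the same data gap around the true change point
        below, above = xs[xs <= 6.2].max(), xs[xs > 6.2].min()
        assert below < thr < above and below < oracle_thr < above
        assert predict_proba(model, X[y]).min() > 0.5 > predict_proba(model, X[~y]).max()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(80, 5)))
        X.columns = [f"f{i}" for i in range(5)]
        y = pd.Series(rng.random(80) < 0.4)
        a = predict_proba(fit_model(X, y, "random_forest", {"n_estimators": 50}, seed=3), X)
        b = predict_proba(fit_model(X, y, "random_forest", {"n_estimators": 50}, seed=3), X)
        assert np.array_equal(a, b)

    def test_single_class_error(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_model(X, pd.Series([True, True]), "logistic")


class TestNestedCV:
    def _separable(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)])
        y = pd.Series(X["f0"].to_numpy() + 0.5 * X["f1"].to_numpy() > 0, name="case")
        # mild imbalance so SMOTE has work to do
        keep = np.where(y)[0][: n // 3].tolist() + np.where(~y)[0].tolist()
        X, y = X.iloc[keep].reset_index(drop=True), y.iloc[keep].reset_index(drop=True)
        X.index = [f"p{i}" for i in range(len(X))]
        y.index = X.index
        return FeatureMatrix(X=X, y=y)

    def _config(self, model="logistic"):
        return MLConfig(
            model=model, outer_folds=3, inner_folds=2, smote_k=3,
            rfe_thresholds=(4,), grid={"C": [1.0]} if model == "logistic" else None,
            seed=5,
        )

    def test_fold_count_and_partition(self):
        fm = self._separable()
        res = nested_cv(fm, self._config())
        assert len(res.fold_metrics) == 3
        all_test_ids = [i for fold in res.test_index_sets for i in fold]
        assert sorted(all_test_ids) == sorted(fm.X.index)  # disjoint partition
        assert all(n > 0 for n in res.n_synthetic_per_fold)  # SMOTE ran on train only

    def test_separable_data_scores_high(self):
        res = nested_cv(self._separable(), self._config())
        assert res.mean("auc") >= 0.95

    def test_selected_features_respect_threshold(self):
        res = nested_cv(self._separable(), self._config())
        assert all(len(cols) == 4 for cols in res.selected_features)

    def test_summary_reports_mean_and_sd(self):
        res = nested_cv(self._separable(), self._config())
        s = res.summary()
        assert "ppv_mean" in s and "ppv_sd" in s and s["ppv_sd"] >= 0.0


class TestShap:
    def test_dummy_feature_gets_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"live": rng.normal(size=30), "dead": np.ones(30)})
        score = lambda arr: arr[:, 0] * 2.0
        report = mean_abs_shap(score, X, X, mc_samples=16, seed=0)
        assert report.mean_abs()["dead"] == pytest.approx(0.0, abs=1e-12)
        assert report.mean_abs()["live"] > 0.1

    def test_symmetric_features_get_equal_attributions(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=200)
        X = pd.DataFrame({"a": v, "b": v})  # interchangeable by construction
        score = lambda arr: arr[:, 0] + arr[:, 1]
        report = mean_abs_shap(score, X, X, mc_samples=200, seed=1)
        ma = report.mean_abs()
        assert ma["a"] == pytest.approx(ma["b"], rel=0.1)

    def test_local_accuracy_exact_against_sampled_baseline(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        score = lambda arr: 1 / (1 + np.exp(-(arr[:, 0] - 2 * arr[:, 2] + arr[:, 3] ** 2)))
        report = mean_abs_shap(score, X, X.iloc[:10], mc_samples=8, seed=2)
        assert np.abs(report.local_accuracy_residuals()).max() < 1e-10

    def test_mc_samples_validation(self):
        X = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            mean_abs_shap(lambda a: a[:, 0], X, X, mc_samples=0)
        with pytest.raises(ValueError):
            mean_abs_shap(lambda a: a[:, 0], X, X.iloc[:0])
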