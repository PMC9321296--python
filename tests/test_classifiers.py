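"""Admission classifiers: tuning, recovery on known generative models, scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from edcast.classifiers import (
    DEFAULT_PARAMS,
    AdmissionClassifier,
    ModelBundle,
    TuningConfig,
    calibration_bins,
    predict_snapshot,
    prediction_metrics,
    train_bundle,
)
from edcast.framing import FEATURE_COLUMNS, FramingConfig, build_left_aligned, build_snapshot
from tests.test_framing import make_visit


def logistic_data(n, beta, seed, n_noise=3):
    """Synthetic logistic-model data with known coefficients and Bayes probabilities."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(beta) + n_noise))
    eta = X[:, : len(beta)] @ np.asarray(beta)
    p = expit(eta)
    y = (rng.random(n) < p).astype(int)
    cols = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols), y, p


class TestLassoLogistic:
    def test_log_loss_approaches_bayes_limit(self):
        """At n=10k, the min-CV-penalty lasso reaches the generative model's log loss."""
        beta = [1.0, -0.8, 0.5]
        X, y, _ = logistic_data(10_000, beta, seed=0)
        X_test, y_test, p_test = logistic_data(10_000, beta, seed=1)
        bayes_ll, _ = prediction_metrics(y_test, p_test)
        clf = AdmissionClassifier(algorithm="lasso_logistic", cv=10, lasso_selection="min")
        clf.fit(X, y)
        model_ll, _ = prediction_metrics(y_test, clf.predict_proba(X_test)[:, 1])
        assert model_ll <= bayes_ll + 0.02

    def test_coefficient_recovery_under_weak_penalty(self):
        """Weakly penalised lasso recovers generative coefficients within 3 SE."""
        import statsmodels.api as sm

        beta = [1.0, -0.8, 0.5]
        X, y, _ = logistic_data(20_000, beta, seed=2, n_noise=2)
        clf = AdmissionClassifier(algorithm="lasso_logistic", params={"C": 100.0})
        clf.fit(X, y)
        # independent SEs from an unpenalised ML fit
        sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        scale = clf.model_.named_steps["scale"].scale_
        coef = clf.model_.named_steps["model"].coef_.ravel() / scale
        for j, b in enumerate(beta):
            se = sm_fit.bse[f"x{j}"]
            assert abs(coef[j] - b) < 3 * se

    def test_regularisation_path_monotone_sparsity(self):
        X, y, _ = logistic_data(4_000, [1.0, -0.8, 0.5, 0.3, -0.2], seed=3, n_noise=5)
        nonzeros = []
        for selection in ("min", "2se", "3se", "4se"):
            clf = AdmissionClassifier(algorithm="lasso_logistic", cv=5,
                                      lasso_selection=selection)
            clf.fit(X, y)
            nonzeros.append(clf.nonzero_coefficients())
        assert all(b <= a for a, b in zip(nonzeros, nonzeros[1:]))


class TestTuning:
    def test_tuned_not_worse_than_untuned_on_average(self):
        """CV-tuned boosted model matches or beats the fixed default, paired over seeds."""
        grid = [
            {"max_depth": 2, "learning_rate": 0.1, "n_estimators": 60},
            {"max_depth": 3, "learning_rate": 0.1, "n_estimators": 100},
            {"max_depth": 6, "learning_rate": 0.3, "n_estimators": 200},
        ]
        diffs = []
        for seed in range(5):
            X, y, _ = logistic_data(2_500, [1.2, -0.8], seed=100 + seed)
            X_test, y_test, _ = logistic_data(4_000, [1.2, -0.8], seed=200 + seed)
            untuned = AdmissionClassifier(params={"max_depth": 6, "learning_rate": 0.3,
                                                  "n_estimators": 200}, random_state=seed)
            tuned = AdmissionClassifier(grid=grid, cv=10, random_state=seed)
            untuned.fit(X, y)
            tuned.fit(X, y)
            ll_u, _ = prediction_metrics(y_test, untuned.predict_proba(X_test)[:, 1])
            ll_t, _ = prediction_metrics(y_test, tuned.predict_proba(X_test)[:, 1])
            diffs.append(ll_t - ll_u)
        assert np.mean(diffs) <= 1e-9

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(60.0)})
        with pytest.raises(ValueError, match="single class"):
            AdmissionClassifier().fit(X, np.ones(60))

    def test_train_bundle_names_offending_cutoff(self, small_stream):
        rows = build_left_aligned(small_stream, 0)
        rows["admitted"] = 1
        with pytest.raises(ValueError, match="cutoff 0"):
            train_bundle({0: rows})


class TestMetrics:
    def test_constant_half_on_balanced_labels(self):
        y = np.array([0, 1] * 50)
        ll, auroc = prediction_metrics(y, np.full(100, 0.5))
        assert ll == pytest.approx(np.log(2), abs=1e-12)
        assert auroc == 0.5

    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0, 1])
        ll, auroc = prediction_metrics(y, y.astype(float))
        assert ll == pytest.approx(0.0, abs=1e-10)
        assert auroc == 1.0

    def test_auroc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        p = rng.random(500)
        y = (rng.random(500) < p).astype(int)
        _, a1 = prediction_metrics(y, p)
        _, a2 = prediction_metrics(y, np.sqrt(p))
        _, a3 = prediction_metrics(y, expit(5 * p - 2))
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert a1 == pytest.approx(a3, abs=1e-12)

    def test_generative_probabilities_are_calibrated(self):
        """Bins built from the true probabilities sit within 3 binomial SE."""
        rng = np.random.default_rng(17)
        p = rng.random(10_000)
        y = (rng.random(10_000) < p).astype(int)
        bins = calibration_bins(y, p)
        se = np.sqrt(bins["predicted_mean"] * (1 - bins["predicted_mean"]) / bins["n"])
        assert (np.abs(bins["observed_rate"] - bins["predicted_mean"]) <= 3 * se).all()


class TestPredictSnapshot:
    def test_empty_snapshot(self, default_bundle):
        snap = build_snapshot([make_visit(arrival=0, duration=10)], 5000)
        assert len(predict_snapshot(default_bundle, snap)) == 0

    def test_patient_at_29_minutes_uses_15_minute_model(self, default_bundle):
        snap = build_snapshot([make_visit(arrival=600, duration=300)], 629)
        preds = predict_snapshot(default_bundle, snap)
        assert preds.iloc[0]["cutoff_used"] == 15

    def test_probabilities_in_unit_interval(self, default_stream, default_bundle):
        snap = build_snapshot(default_stream, 100 * 1440 + 960)
        preds = predict_snapshot(default_bundle, snap)
        assert len(preds) == len(snap)
        assert ((preds["p_admit"] >= 0) & (preds["p_admit"] <= 1)).all()

    def test_schema_mismatch_names_features(self, default_bundle):
        snap = build_snapshot([make_visit(arrival=600, duration=300)], 700)
        broken = snap.rows.drop(columns=["n_consults"]).rename(columns={"latest_crp": "bogus"})
        clf = default_bundle.models[90]
        with pytest.raises(ValueError, match="n_consults"):
            clf.predict_proba(broken[[c for c in broken.columns if c not in
                                      ("visit_id", "elapsed_minutes", "cutoff_minutes")]])


class TestBundlePersistence:
    def test_save_load_round_trip(self, tmp_path, small_stream):
        fc = FramingConfig()
        rows = {c: build_left_aligned(small_stream, c, fc) for c in (0, 60)}
        fc_small = FramingConfig(cutoffs_minutes=(0, 60))
        bundle = train_bundle(rows)
        bundle.save(tmp_path / "bundle")
        again = ModelBundle.load(tmp_path / "bundle")
        snap = build_snapshot(small_stream, 10 * 1440 + 960, fc_small)
        a = predict_snapshot(bundle, snap)
        b = predict_snapshot(again, snap)
        pd.testing.assert_frame_equal(a, b)

    def test_importance_table_groups(self, default_bundle):
        table = default_bundle.importance_table()
        assert set(table["group"]) <= {"visit", "location", "observations_consults", "pathology"}
        assert list(table.columns[1:]) == [f"T{c}" for c in default_bundle.cutoffs]
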