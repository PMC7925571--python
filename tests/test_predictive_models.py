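import numpy as np
import pytest

from connectopath.connectome_io import ValidationError
from connectopath.predictive_models import (
    FeatureTable,
    SMALL_C_GRID,
    assemble_features,
    importance_classification,
    importance_regression,
    loess_fit,
    loocv_evaluate,
    permutation_test,
    summarize_top_regions,
    train_linear_svm,
    _fold_standardize,
)
from connectopath.pipeline import RunConfig, compute_all_metrics
from connectopath.synthetic_cohort import SimulationConfig, simulate_cohort


def class_table(X, labels, names=None):
    n, p = X.shape
    return FeatureTable(
        subject_ids=tuple(f"s{i}" for i in range(n)),
        feature_names=tuple(names or (f"f{j}" for j in range(p))),
        values=X,
        outcome=np.asarray(labels),
        task="classification",
    )


def reg_table(X, y, names=None):
    n, p = X.shape
    return FeatureTable(
        subject_ids=tuple(f"s{i}" for i in range(n)),
        feature_names=tuple(names or (f"f{j}" for j in range(p))),
        values=X,
        outcome=np.asarray(y, dtype=float),
        task="regression",
    )


class TestTrainLinearSvm:
    def test_separable_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        y = np.array(["ADHD"] * 20 + ["TDC"] * 20)
        model = train_linear_svm(X, y, C=1.0, task="classification")
        assert np.mean(model.predict(X) == y) == 1.0

    def test_svr_recovers_slope_within_epsilon_tube(self):
        x = np.linspace(-2, 2, 50).reshape(-1, 1)
        y = 3.0 * x.ravel()
        model = train_linear_svm(x, y, C=100.0, task="regression", epsilon=0.1)
        assert 2.9 < model.coef_[0][0] < 3.1

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            train_linear_svm(np.zeros((4, 2)), np.array(["A"] * 4), 1.0, "classification")

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ValidationError):
            train_linear_svm(np.zeros((4, 2)), np.array(["A", "B"] * 2), 0.0, "classification")

    def test_sigma_not_implemented(self):
        with pytest.raises(NotImplementedError):
            train_linear_svm(
                np.zeros((4, 2)), np.array(["A", "B"] * 2), 1.0, "classification", sigma=0.5
            )


class TestLoocv:
    def test_separable_classes_perfect_loocv(self):
        rng = np.random.default_rng(1)
        n = 40
        X = rng.normal(size=(n, 5))
        labels = np.array(["ADHD"] * 20 + ["TDC"] * 20)
        X[:20, 0] += 8.0  # widely separated clouds: any margin classifier separates
        ev = loocv_evaluate(class_table(X, labels), C_grid=SMALL_C_GRID)
        assert ev.accuracy_stats.accuracy_pct == 100.0
        assert len(ev.loocv_predictions) == n

    def test_planted_d3_effect_high_accuracy(self):
        rng = np.random.default_rng(1)
        n = 40
        X = rng.normal(size=(n, 5))
        labels = np.array(["ADHD"] * 20 + ["TDC"] * 20)
        X[:20, 0] += 3.0  # d = 3 still leaves a little class overlap
        ev = loocv_evaluate(class_table(X, labels), C_grid=SMALL_C_GRID)
        assert ev.accuracy_stats.accuracy_pct >= 80.0

    def test_pure_noise_accuracy_in_binomial_band(self):
        rng = np.random.default_rng(2)
        n = 40
        X = rng.normal(size=(n, 10))
        labels = np.array(["ADHD", "TDC"] * 20)
        ev = loocv_evaluate(class_table(X, labels), C_grid=SMALL_C_GRID)
        # central 95% band around 0.5 for n=40 is roughly [0.34, 0.66];
        # tuning over C inflates slightly, allow a generous band
        assert 20.0 <= ev.accuracy_stats.accuracy_pct <= 80.0

    def test_near_deterministic_regression_signal(self):
        rng = np.random.default_rng(3)
        n = 40
        X = rng.normal(size=(n, 4))
        y = X[:, 0] + rng.normal(0, 0.01, n)
        ev = loocv_evaluate(reg_table(X, y), C_grid=SMALL_C_GRID)
        assert ev.obs_pred_r > 0.95

    def test_one_prediction_per_subject(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        labels = np.array(["ADHD", "TDC"] * 6)
        ev = loocv_evaluate(class_table(X, labels), C_grid=[1.0])
        assert sorted(ev.loocv_predictions) == sorted(f"s{i}" for i in range(12))

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValidationError):
            loocv_evaluate(class_table(np.zeros((3, 2)), ["A", "B", "A"]))

    def test_fold_standardization_uses_train_only(self):
        rng = np.random.default_rng(5)
        Xtr = rng.normal(size=(10, 3))
        Xte = rng.normal(size=(1, 3)) + 100.0  # outlier test row
        Ztr, Zte = _fold_standardize(Xtr, Xte)
        # train stats unaffected by the test row
        assert np.allclose(Ztr.mean(axis=0), 0, atol=1e-12)
        assert np.all(Zte > 50)  # test row stays extreme under train scaling


class TestPermutation:
    def test_minimum_attainable_p(self):
        # strong planted effect, tiny B: observed beats every permutation
        rng = np.random.default_rng(6)
        n = 24
        X = rng.normal(size=(n, 3))
        labels = np.array(["ADHD"] * 12 + ["TDC"] * 12)
        X[:12, 0] += 5.0
        p = permutation_test(class_table(X, labels), C_grid=[1.0], B=19, seed=0)
        assert p == pytest.approx(1 / 20)

    def test_null_p_is_large(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        labels = np.array(["ADHD", "TDC"] * 10)
        p = permutation_test(class_table(X, labels), C_grid=[1.0], B=39, seed=1)
        assert p > 0.1

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(16, 4))
        labels = np.array(["ADHD", "TDC"] * 8)
        t = class_table(X, labels)
        p1 = permutation_test(t, C_grid=[1.0], B=25, seed=42)
        p2 = permutation_test(t, C_grid=[1.0], B=25, seed=42)
        assert p1 == p2

    def test_invariant_to_feature_column_order(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(16, 4))
        X[:8, 1] += 2.0
        labels = np.array(["ADHD"] * 8 + ["TDC"] * 8)
        t1 = class_table(X, labels)
        perm = [3, 1, 0, 2]
        t2 = class_table(X[:, perm], labels, names=[f"f{j}" for j in perm])
        p1 = permutation_test(t1, C_grid=[1.0], B=25, seed=3)
        p2 = permutation_test(t2, C_grid=[1.0], B=25, seed=3)
        assert p1 == p2


class TestImportanceClassification:
    def test_class_indicator_feature_scores_one(self):
        labels = np.array(["ADHD"] * 5 + ["TDC"] * 5)
        X = np.column_stack([(labels == "ADHD").astype(float)])
        entries = importance_classification(class_table(X, labels))
        assert entries[0]["score"] == pytest.approx(1.0)

    def test_constant_feature_scores_half(self):
        labels = np.array(["ADHD"] * 5 + ["TDC"] * 5)
        X = np.ones((10, 1))
        entries = importance_classification(class_table(X, labels))
        assert entries[0]["score"] == pytest.approx(0.5)

    def test_fully_concordant_pairs(self):
        labels = np.array(["ADHD"] * 3 + ["TDC"] * 3)
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        entries = importance_classification(class_table(X, labels))
        assert entries[0]["score"] == pytest.approx(1.0)
        assert entries[0]["direction"] == "ADHD_lower"

    def test_matches_brute_force_mann_whitney(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(6, 31))
            n_a = int(rng.integers(2, n - 1))
            labels = np.array(["ADHD"] * n_a + ["TDC"] * (n - n_a))
            x = np.round(rng.normal(size=n), 1)  # ties likely
            entries = importance_classification(class_table(x.reshape(-1, 1), labels))
            a, b = x[:n_a], x[n_a:]
            u = sum(
                1.0 if ai > bi else (0.5 if ai == bi else 0.0) for ai in a for bi in b
            )
            auc = u / (len(a) * len(b))
            assert entries[0]["score"] == pytest.approx(max(auc, 1 - auc), abs=1e-12)


class TestImportanceRegression:
    def test_exact_signal_scores_near_one(self):
        x = np.linspace(0, 1, 30)
        entries = importance_regression(reg_table(x.reshape(-1, 1), x * 5 - 1))
        assert entries[0]["score"] > 0.99

    def test_independent_outcome_scores_near_zero(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=(200, 1))
            y = rng.normal(size=200)
            entries = importance_regression(reg_table(x, y))
            hits += entries[0]["score"] < 0.1
        assert hits >= 18

    def test_quadratic_beats_linear_r2(self):
        x = np.linspace(-1, 1, 40)
        y = x**2
        entries = importance_regression(reg_table(x.reshape(-1, 1), y))
        lin_r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert entries[0]["score"] > 0.9
        assert entries[0]["score"] > lin_r2 + 0.5

    def test_constant_feature_flagged_zero(self):
        entries = importance_regression(reg_table(np.ones((15, 1)), np.arange(15.0)))
        assert entries[0]["score"] == 0.0
        assert entries[0].get("flagged")

    def test_loess_interpolates_smooth_function(self):
        x = np.linspace(0, 2 * np.pi, 60)
        y = np.sin(x)
        fitted = loess_fit(x, y, span=0.3)
        assert np.max(np.abs(fitted - y)) < 0.05


class TestAssembleAndSummarize:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_cohort_metrics():
        cfg = SimulationConfig(n_adhd=6, n_tdc=5, n_regions=82, seed=21)
        cohort, truth = simulate_cohort(cfg)
        config = RunConfig(thresholds=(0.1, 0.2, 0.3), permutations=0)
        return cohort, compute_all_metrics(cohort, config), truth

    def test_diagnostic_covariates_add_two_columns(self, small_cohort_metrics):
        cohort, metrics, _ = small_cohort_metrics
        t = assemble_features(metrics, cohort, task="diagnosis", include_covariates=True)
        assert len(t.feature_names) == 84
        assert t.feature_names[-2:] == ("age", "gender")

    def test_treatment_covariates_add_six_columns(self, small_cohort_metrics):
        cohort, metrics, _ = small_cohort_metrics
        t = assemble_features(metrics, cohort, task="response", include_covariates=True)
        assert len(t.feature_names) == 88

    def test_no_covariates_gives_82_columns(self, small_cohort_metrics):
        cohort, metrics, _ = small_cohort_metrics
        t = assemble_features(metrics, cohort, task="diagnosis", include_covariates=False)
        assert len(t.feature_names) == 82

    def test_missing_metrics_rejected(self, small_cohort_metrics):
        cohort, metrics, _ = small_cohort_metrics
        partial = {k: v for k, v in list(metrics.items())[:-1]}
        with pytest.raises(ValidationError, match="missing graph metrics"):
            assemble_features(partial, cohort, task="diagnosis")

    def test_summarize_top_regions_census(self, atlas82):
        # plant 5 subcortical + 5 cortical leading features
        names = [f"leff_{r}_auc" for r in atlas82.names]
        sc = [n for n, net in zip(names, [atlas82.network_of(r) for r in atlas82.names]) if net == "subcortical"]
        cort = [n for n in names if n not in sc]
        importance = [
            {"feature": f, "score": 1.0 - 0.01 * i, "direction": "ADHD_lower"}
            for i, f in enumerate(sc[:5] + cort[:5])
        ] + [
            {"feature": f, "score": 0.5, "direction": "ADHD_lower"}
            for f in cort[5:]
        ]
        report = summarize_top_regions(importance, atlas82, k=10)
        assert report["fraction_subcortical"] == pytest.approx(0.5)
        assert len(report["top_regions"]) == 10

    def test_summarize_k1(self, atlas82):
        importance = [{"feature": f"leff_{atlas82.names[0]}_auc", "score": 1.0, "direction": "x"}]
        report = summarize_top_regions(importance, atlas82, k=1)
        assert len(report["top_regions"]) == 1

    def test_summarize_k_too_large_rejected(self, atlas82):
        importance = [{"feature": f"leff_{atlas82.names[0]}_auc", "score": 1.0, "direction": "x"}]
        with pytest.raises(ValidationError):
            summarize_top_regions(importance, atlas82, k=2)

    def test_summarize_k_nonpositive_rejected(self, atlas82):
        with pytest.raises(ValidationError):
            summarize_top_regions([], atlas82, k=0)


class TestLeakageGuard:
    def test_null_outcome_with_noise_features_stays_in_band(self):
        """LOOCV tuning must not leak the held-out subject: under a null
        outcome the held-out accuracy stays inside the binomial band even
        with many features and C tuning."""
        rng = np.random.default_rng(12)
        n = 40
        accs = []
        for rep in range(5):
            X = rng.normal(size=(n, 30))
            labels = np.array(["ADHD", "TDC"] * (n // 2))
            ev = loocv_evaluate(class_table(X, labels), C_grid=SMALL_C_GRID)
            accs.append(ev.accuracy_stats.accuracy_pct / 100)
        # mean of 5 null accuracies: generous 99% band around 0.5
        assert 0.3 < np.mean(accs) < 0.7
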