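import numpy as np
import pytest

from oracles import naive_auc
from periradiomics.classify import (
    CLASSIFIER_KINDS,
    DiagonalLDA,
    binary_metrics,
    cross_validate,
    evaluate_holdout,
    sequential_feature_eval,
    train_classifier,
)
from periradiomics.synthetic import generate_feature_table


class TestBinaryMetrics:
    def test_scores_equal_labels_perfect(self):
        m = binary_metrics(np.array([1.0, 1, 0, 0]), np.array([1, 1, 0, 0]))
        assert (m["auc"], m["accuracy"], m["sensitivity"], m["specificity"]) == (1, 1, 1, 1)

    def test_tied_scores_give_half_auc(self):
        m = binary_metrics(np.full(6, 0.7), np.array([1, 1, 1, 0, 0, 0]))
        assert m["auc"] == 0.5

    def test_rank_oracle_and_monotone_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]  # both classes present
        a = binary_metrics(scores, labels)["auc"]
        assert a == pytest.approx(naive_auc(scores, labels))
        b = binary_metrics(np.exp(3 * scores), labels)["auc"]
        assert b == pytest.approx(a)

    def test_separable_quartet(self):
        m = binary_metrics(np.array([0.9, 0.8, 0.3, 0.2]), np.array([1, 1, 0, 0]))
        assert m["auc"] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics(np.array([0.1, 0.9]), np.array([1, 1]))


class TestClassifiers:
    def test_dlda_threshold_at_midpoint_of_means(self):
        """Equal-variance 1D classes: the decision boundary sits at the
        midpoint of the class means (closed-form discriminant)."""
        rngd = np.random.default_rng(0)
        x0 = rngd.normal(0.0, 1.0, 200)
        x1 = rngd.normal(4.0, 1.0, 200)
        X = np.concatenate([x0, x1])[:, None]
        y = np.array([0] * 200 + [1] * 200)
        model = DiagonalLDA().fit(X, y)
        mid = (x0.mean() + x1.mean()) / 2
        p = model.predict_proba(np.array([[mid]]))[0, 1]
        assert p == pytest.approx(0.5, abs=1e-6)
        assert model.predict(np.array([[mid - 0.5], [mid + 0.5]])).tolist() == [0, 1]

    def test_perfect_separation_training_auc_one_for_all_kinds(self, rng):
        X = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 5]) + 0.1 * rng.normal(size=(20, 2))
        y = np.array([0] * 10 + [1] * 10)
        for kind in CLASSIFIER_KINDS:
            model = train_classifier(kind, X, y)
            if hasattr(model, "predict_proba"):
                s = model.predict_proba(X)[:, 1]
            else:
                s = model.decision_function(X)
            assert binary_metrics(s, y, 0.5 if hasattr(model, "predict_proba") else 0.0)["auc"] == 1.0

    def test_lda_equals_dlda_on_axis_aligned_data(self):
        """When the pooled covariance is diagonal by construction the two
        discriminants produce the same posteriors."""
        rngd = np.random.default_rng(1)
        n = 2000
        blocks = []
        for mean in ([0, 0], [2, 1]):
            Z = rngd.normal(size=(n, 2))
            Z -= Z.mean(axis=0)
            # whiten so the within-class sample covariance is exactly diagonal
            C = np.cov(Z, rowvar=False)
            Z = Z @ np.linalg.inv(np.linalg.cholesky(C)).T
            blocks.append(Z * [1.0, 2.0] + mean)
        X = np.vstack(blocks)
        y = np.array([0] * n + [1] * n)
        p_lda = train_classifier("LDA", X, y).predict_proba(X[:50])[:, 1]
        p_dlda = train_classifier("DLDA", X, y).predict_proba(X[:50])[:, 1]
        assert np.allclose(p_lda, p_dlda, atol=2e-3)

    def test_singular_covariance_falls_back_with_warning(self, rng):
        X = rng.normal(size=(12, 8))  # 6 per class < 8 features
        y = np.array([0] * 6 + [1] * 6)
        with pytest.warns(UserWarning, match="singular"):
            model = train_classifier("QDA", X, y)
        assert np.isfinite(model.predict_proba(X)).all()


class TestCrossValidation:
    def test_null_auc_near_half(self):
        """Chance-level check averaged over independent null cohorts: a
        single finite dataset carries chance feature-label correlations of
        order +/-0.08 AUC, so the 0.5 +/- 0.05 band applies to the mean."""
        aucs = []
        for seed in range(8):
            table, y = generate_feature_table(100, 10, 0, 0.0, seed=seed)
            rep = cross_validate(table, y, table.columns, "DLDA", n_repeats=10, seed=0)
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_planted_effect_all_classifiers_strong(self):
        table, y = generate_feature_table(100, 5, 5, 2.0, seed=7)
        for kind in CLASSIFIER_KINDS:
            rep = cross_validate(table, y, table.columns, kind, n_repeats=10, seed=0)
            assert rep.auc > 0.85, kind

    def test_report_carries_mean_and_sd(self):
        table, y = generate_feature_table(60, 3, 3, 1.0, seed=8)
        rep = cross_validate(table, y, table.columns, "LDA", n_repeats=5, seed=0)
        assert rep.auc_sd >= 0.0
        assert 0.0 <= rep.auc <= 1.0
        assert rep.mode == "cv"

    def test_classifier_robustness_within_band(self):
        """All five classifiers land within 0.1 AUC of one another on the
        planted-effect cohort (median over seeds)."""
        per_kind = {k: [] for k in CLASSIFIER_KINDS}
        for seed in range(5):
            table, y = generate_feature_table(100, 5, 5, 1.2, seed=100 + seed)
            for kind in CLASSIFIER_KINDS:
                rep = cross_validate(table, y, table.columns, kind, n_repeats=5, seed=seed)
                per_kind[kind].append(rep.auc)
        medians = [np.median(v) for v in per_kind.values()]
        assert max(medians) - min(medians) < 0.1


class TestHoldout:
    def test_degenerate_holdout_equals_resubstitution(self):
        table, y = generate_feature_table(80, 4, 4, 1.5, seed=9)
        rep = evaluate_holdout(table, y, table, y, table.columns, "DLDA")
        model = train_classifier("DLDA", table.values, y)
        scores = model.predict_proba(table.values)[:, 1]
        resub = binary_metrics(scores, y)
        assert rep.auc == pytest.approx(resub["auc"])
        assert rep.accuracy == pytest.approx(resub["accuracy"])

    def test_holdout_tracks_cv_on_planted_cohort(self):
        """Across seeds, median |holdout AUC - CV AUC| stays within 0.1."""
        gaps = []
        for seed in range(6):
            tr, ytr = generate_feature_table(78, 6, 6, 1.2, seed=seed, positive_fraction=24 / 78)
            te, yte = generate_feature_table(39, 6, 6, 1.2, seed=5000 + seed, positive_fraction=12 / 39)
            cv = cross_validate(tr, ytr, tr.columns, "DLDA", n_repeats=10, seed=seed)
            ho = evaluate_holdout(tr, ytr, te, yte, tr.columns, "DLDA")
            gaps.append(abs(ho.auc - cv.auc))
        assert np.median(gaps) < 0.1

    def test_label_permuted_holdout_near_chance(self, rng):
        tr, ytr = generate_feature_table(78, 6, 6, 1.5, seed=3)
        te, yte = generate_feature_table(100, 6, 6, 1.5, seed=4)
        aucs = []
        for _ in range(10):
            yperm = rng.permutation(yte)
            aucs.append(evaluate_holdout(tr, ytr, te, yperm, tr.columns, "DLDA").auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1


class TestSequentialInclusion:
    def test_prefix_one_matches_single_feature_cv(self):
        table, y = generate_feature_table(60, 5, 5, 1.0, seed=11)
        ranked = table.columns
        reports = sequential_feature_eval(table, y, ranked, "LDA", n_repeats=3, seed=2)
        single = cross_validate(table, y, ranked[:1], "LDA", n_repeats=3, seed=2)
        assert reports[0].auc == pytest.approx(single.auc)
        assert reports[0].n_features_used == 1

    def test_ten_reports_for_ten_features(self):
        table, y = generate_feature_table(60, 12, 6, 1.0, seed=12)
        reports = sequential_feature_eval(table, y, table.columns[:10], "DLDA", n_repeats=2)
        assert len(reports) == 10
        assert [r.n_features_used for r in reports] == list(range(1, 11))

    def test_independent_informative_features_give_nondecreasing_auc(self):
        """Median AUC over seeds does not decrease as independent planted
        features accumulate."""
        aucs = []
        for seed in range(5):
            table, y = generate_feature_table(90, 6, 6, 0.8, seed=200 + seed)
            reports = sequential_feature_eval(table, y, table.columns, "DLDA", n_repeats=5, seed=seed)
            aucs.append([r.auc for r in reports])
        med = np.median(np.array(aucs), axis=0)
        assert np.all(np.diff(med) > -0.03)  # monotone up to CV noise
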