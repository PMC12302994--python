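"""Cross-validation machinery: fold construction, AUC against a
brute-force oracle, confusion matrices and the metric set."""

import numpy as np
import pandas as pd
import pytest

from skinraman.evaluation import (
    binary_confusion_and_metrics,
    confusion_matrix_multiclass,
    cross_validate,
    make_grouped_stratified_folds,
    ovr_auc,
)

SEED = 11


def brute_force_auc(scores, positives):
    """Oracle: P(random positive outscores random negative), ties half."""
    pos = scores[positives]
    neg = scores[~positives]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestFolds:
    def test_balanced_partition(self):
        patients = np.repeat([f"P{i}" for i in range(10)], 3)
        labels = np.tile(["A", "B"], 15)
        # give each patient a single majority label
        labels = np.repeat(["A", "B"] * 5, 3)
        folds = make_grouped_stratified_folds(patients, labels, k=5, seed=SEED)
        per_fold = pd.Series(folds.patient_fold).value_counts()
        assert (per_fold == 2).all()

    def test_patient_disjointness(self):
        rng = np.random.default_rng(SEED)
        patients = rng.choice([f"P{i}" for i in range(20)], size=100)
        labels = np.array(["A" if p < "P5" else "B" for p in patients])
        folds = make_grouped_stratified_folds(patients, labels, k=5, seed=SEED)
        for f in range(5):
            inside = set(patients[folds.spectrum_fold == f])
            outside = set(patients[folds.spectrum_fold != f])
            assert not inside & outside

    def test_label_proportions_within_one_patient(self):
        """On a 20-patient balanced fixture, each fold's label counts are
        within +/-1 patient of the global proportion."""
        patients = np.array([f"P{i}" for i in range(20)])
        labels = np.repeat(["A", "B"], 10)
        folds = make_grouped_stratified_folds(patients, labels, k=5, seed=SEED)
        for f in range(5):
            for lab in ("A", "B"):
                n = np.sum((folds.spectrum_fold == f) & (labels == lab))
                assert abs(n - 2) <= 1

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            make_grouped_stratified_folds(["P1", "P2"], ["A", "B"], k=5)


class TestOvrAuc:
    def test_perfect_ranking(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        labels = np.array(["a", "a", "b", "b"])
        per_class, macro = ovr_auc(scores, labels, ("a", "b"))
        assert per_class == {"a": 1.0, "b": 1.0} and macro == 1.0

    def test_four_point_toy_case(self):
        """pos {0.9, 0.8}, neg {0.85, 0.1}: 3 wins of 4 pairs -> 0.75."""
        scores = np.array([[0.9], [0.8], [0.85], [0.1]])
        labels = np.array(["p", "p", "n", "n"])
        per_class, _ = ovr_auc(
            np.column_stack([scores[:, 0], 1 - scores[:, 0]]), labels, ("p",)
        )
        assert per_class["p"] == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(SEED)
        scores = rng.uniform(size=(1000, 2))
        labels = rng.choice(["a", "b"], size=1000)
        _, macro = ovr_auc(scores, labels, ("a", "b"))
        assert macro == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_oracle_with_ties(self):
        """Exact agreement with pairwise enumeration on random instances
        with heavy ties (scores drawn from a 5-point lattice)."""
        rng = np.random.default_rng(SEED)
        for _ in range(50):
            n = rng.integers(4, 50)
            s = rng.integers(0, 5, size=n) / 4.0
            labels = rng.choice(["x", "y"], size=n)
            if len(set(labels)) < 2:
                continue
            per_class, _ = ovr_auc(
                np.column_stack([s, 1 - s]), labels, ("x", "y")
            )
            assert per_class["x"] == pytest.approx(
                brute_force_auc(s, labels == "x"), abs=1e-12
            )

    def test_degenerate_class_excluded_with_warning(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2]])
        labels = np.array(["a", "a"])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            per_class, macro = ovr_auc(scores, labels, ("a", "b"))
        assert np.isnan(per_class["a"]) and np.isnan(per_class["b"])
        assert np.isnan(macro)


class TestConfusionMatrices:
    def test_all_correct_is_diagonal(self):
        scores = np.eye(3)
        labels = np.array(["a", "b", "c"])
        counts, props = confusion_matrix_multiclass(scores, labels, ("a", "b", "c"))
        assert np.array_equal(counts, np.eye(3, dtype=int))
        assert np.array_equal(props, np.eye(3))

    def test_hand_checked_three_sample_example(self):
        scores = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.1, 0.7, 0.2]])
        labels = np.array(["a", "b", "c"])  # argmaxes: a, b, b
        counts, props = confusion_matrix_multiclass(scores, labels, ("a", "b", "c"))
        assert np.array_equal(counts, [[1, 0, 0], [0, 1, 0], [0, 1, 0]])
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_row_sums_equal_class_counts(self):
        rng = np.random.default_rng(SEED)
        scores = rng.uniform(size=(60, 4))
        labels = rng.choice(list("abcd"), size=60)
        counts, _ = confusion_matrix_multiclass(scores, labels, tuple("abcd"))
        for i, cls in enumerate("abcd"):
            assert counts[i].sum() == np.sum(labels == cls)


class TestBinaryMetrics:
    def test_perfect_scores(self):
        m = binary_confusion_and_metrics(np.array([0.9, 0.8, 0.1]), [1, 1, 0])
        for key in ("recall", "sensitivity", "specificity", "accuracy", "precision"):
            assert m[key] == 1.0

    def test_all_negative_predictions(self):
        m = binary_confusion_and_metrics(np.array([0.2, 0.3, 0.1]), [1, 1, 0])
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0

    def test_printed_two_by_two_example(self):
        """TP=3, FP=1, FN=1, TN=5: precision .75, sensitivity .75,
        specificity 5/6, accuracy .8; recall == sensitivity."""
        scores = np.array([0.9, 0.9, 0.9, 0.2, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        m = binary_confusion_and_metrics(scores, labels)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (3, 1, 1, 5)
        assert m["precision"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["recall"] == m["sensitivity"]
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["accuracy"] == pytest.approx(0.8)


class TestCrossValidate:
    def test_out_of_fold_coverage_and_exclusions(self, tiny_processed):
        cv = cross_validate(tiny_processed, "knn", classes=4, seed=SEED)
        # 4-class setup drops all SCC spectra (TUM-T + SCC EPI-H)
        n_scc = int((tiny_processed.manifest["lesion"] == "SCC").sum())
        assert cv.report.n_excluded == n_scc
        assert cv.oof_scores.shape == (len(tiny_processed) - n_scc, 4)
        assert not np.isnan(cv.oof_scores).any()
        assert np.allclose(cv.oof_scores.sum(axis=1), 1.0, atol=1e-6)

    def test_metrics_consistent_with_confusion_matrix(self, tiny_processed):
        cv = cross_validate(tiny_processed, "knn", classes=5, seed=SEED)
        counts = cv.report.confusion_counts
        assert counts.sum() == cv.report.n_spectra
        # recompute binary metrics from the out-of-fold scores: must match
        for j, cls in enumerate(cv.class_order):
            m = binary_confusion_and_metrics(cv.oof_scores[:, j], cv.labels == cls)
            for key in ("sensitivity", "specificity", "accuracy"):
                assert m[key] == cv.report.binary_metrics[cls][key]

    def test_report_summary_renders(self, tiny_processed):
        cv = cross_validate(tiny_processed, "knn", classes=5, seed=SEED)
        text = cv.report.summary()
        assert "macro one-vs-rest AUC" in text
        for cls in cv.class_order:
            assert cls in text

    def test_invalid_class_setup_rejected(self, tiny_processed):
        with pytest.raises(ValueError, match="classes"):
            cross_validate(tiny_processed, "knn", classes=3)
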