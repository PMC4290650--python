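import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import multitox as mt
from multitox.data_model import DataError
from multitox.evaluation import (
    _candidate_thresholds,
    choose_threshold,
    compute_auc,
    make_drug_folds,
    roc_curve_points,
    run_cross_validation,
    sensitivity_specificity,
)


class TestDrugFolds:
    def test_even_split(self):
        folds = make_drug_folds([f"d{i}" for i in range(10)], 5, seed=0)
        assert folds.fold_sizes() == [2] * 5

    def test_remainder_rule(self):
        folds = make_drug_folds([f"d{i}" for i in range(11)], 5, seed=1)
        assert sorted(folds.fold_sizes()) == [2, 2, 2, 2, 3]

    def test_every_drug_in_exactly_one_fold(self):
        drugs = [f"d{i}" for i in range(13)]
        folds = make_drug_folds(drugs, 4, seed=2)
        seen = [d for f in range(4) for d in folds.drugs_in_fold(f)]
        assert sorted(seen) == sorted(drugs)

    def test_too_many_folds_is_error(self):
        with pytest.raises(DataError):
            make_drug_folds(["d0", "d1"], 3, seed=0)


def exhaustive_gmean(scores, labels):
    """Oracle: best geometric mean over all unique-score candidates plus
    an all-positive threshold below the minimum."""
    best = 0.0
    for thr in np.concatenate(([-np.inf], np.unique(scores))):
        sens, spec = sensitivity_specificity(scores, labels, thr)
        best = max(best, np.sqrt(sens * spec))
    return best


class TestChooseThreshold:
    def test_perfect_separation(self):
        scores = np.array([0.1] * 5 + [0.9] * 5)
        labels = np.array([0] * 5 + [1] * 5)
        thr = choose_threshold(scores, labels)
        sens, spec = sensitivity_specificity(scores, labels, thr)
        assert sens == 1.0 and spec == 1.0

    def test_degenerate_identical_scores_returns_lowest_candidate(self):
        scores = np.full(6, 0.5)
        labels = np.array([0, 1, 0, 1, 0, 1])
        thr = choose_threshold(scores, labels)
        assert thr == _candidate_thresholds(scores)[0] == pytest.approx(-0.5)

    def test_single_class_is_error(self):
        with pytest.raises(DataError):
            choose_threshold(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = np.round(rng.uniform(0, 1, 200), 2)  # force ties
            labels = rng.integers(0, 2, 200)
            if labels.min() == labels.max():
                continue
            thr = choose_threshold(scores, labels)
            sens, spec = sensitivity_specificity(scores, labels, thr)
            assert np.sqrt(sens * spec) == pytest.approx(
                exhaustive_gmean(scores, labels), abs=1e-12
            )


def pair_counting_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_and_reversed_ranking(self):
        labels = np.array([0, 0, 1, 1])
        assert compute_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels) == 1.0
        assert compute_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels) == 0.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = np.round(rng.uniform(0, 1, 60), 1)
            labels = rng.integers(0, 2, 60)
            if labels.min() == labels.max():
                continue
            assert compute_auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        assert compute_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(10, dtype=int), rng.integers(0, 2, 20)]
        transformed = np.exp(3 * scores) + 1
        assert compute_auc(scores, labels) == pytest.approx(
            compute_auc(transformed, labels), abs=1e-12
        )

    def test_roc_curve_integrates_to_auc(self):
        rng = np.random.default_rng(3)
        scores = np.round(rng.uniform(0, 1, 80), 1)
        labels = rng.integers(0, 2, 80)
        fpr, tpr = roc_curve_points(scores, labels)
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert np.trapezoid(tpr, fpr) == pytest.approx(
            compute_auc(scores, labels), abs=1e-12
        )


class TestCrossValidation:
    def test_contract_on_synthetic_data(self, small_dataset, small_config):
        expr, ann, occ = small_dataset
        report = run_cross_validation(expr, ann, occ, small_config)
        frame = report.metrics_frame()
        assert set(frame["scorer"]) == {"PPS", "IPS"}
        for col in ("sensitivity", "specificity", "auc"):
            vals = frame[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
        for detail in report.fold_details:
            assert not set(detail.train_drugs) & set(detail.test_drugs)

    def test_repeated_runs_are_identical(self, small_dataset, small_config):
        expr, ann, occ = small_dataset
        a = run_cross_validation(expr, ann, occ, small_config)
        b = run_cross_validation(expr, ann, occ, small_config)
        assert a.metrics_frame().equals(b.metrics_frame())
        assert a.per_fold_frame().equals(b.per_fold_frame())

    def test_identity_similarity_gives_equal_pps_and_ips(
        self, orthogonal_findings_dataset
    ):
        expr, ann, occ = orthogonal_findings_dataset
        config = mt.StudyConfig(n_submodels=5, knn_k=3, cv_folds=3, random_seed=1)
        report = run_cross_validation(expr, ann, occ, config)
        for detail in report.fold_details:
            np.testing.assert_array_equal(detail.similarity, np.eye(2))
        for fe in report.findings:
            assert fe.metrics["IPS"].sensitivity == fe.metrics["PPS"].sensitivity
            assert fe.metrics["IPS"].specificity == fe.metrics["PPS"].specificity
            assert fe.metrics["IPS"].auc == fe.metrics["PPS"].auc

    def test_misaligned_inputs_are_rejected(self, small_dataset, small_config):
        expr, ann, occ = small_dataset
        bad_ann = mt.SampleAnnotation(["zz"], ["d"], ["liver"])
        with pytest.raises(DataError):
            run_cross_validation(expr, bad_ann, occ, small_config)
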