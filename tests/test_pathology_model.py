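import numpy as np
import pytest

import multitox as mt
from multitox.data_model import DataError
from multitox.pathology_model import (
    KnnSubModel,
    UntrainableFindingError,
    _neighbor_scores,
    compute_pps,
    compute_pps_batch,
    draw_jackknife_samples,
    submodel_score,
    train_pathology_model,
)

FINDING = mt.PathologyFinding("liver", "Necrosis")


class TestJackknife:
    def test_every_sample_contains_all_cases(self):
        cases = [f"c{i}" for i in range(5)]
        controls = [f"k{i}" for i in range(100)]
        samples = draw_jackknife_samples(cases, controls, n=10, subset_size=5, seed=0)
        assert len(samples) == 10
        for jk in samples:
            assert jk.case_ids == cases
            assert len(jk.control_ids) == 5
            assert set(jk.control_ids) <= set(controls)
            assert len(jk.sample_ids) == 10

    def test_same_seed_reproduces(self):
        a = draw_jackknife_samples(["c"] * 0 + ["c1", "c2"], [f"k{i}" for i in range(30)],
                                   n=6, subset_size=4, seed=9)
        b = draw_jackknife_samples(["c1", "c2"], [f"k{i}" for i in range(30)],
                                   n=6, subset_size=4, seed=9)
        assert [jk.control_ids for jk in a] == [jk.control_ids for jk in b]
        c = draw_jackknife_samples(["c1", "c2"], [f"k{i}" for i in range(30)],
                                   n=6, subset_size=4, seed=10)
        assert [jk.control_ids for jk in a] != [jk.control_ids for jk in c]

    def test_oversized_subset_is_error(self):
        with pytest.raises(DataError):
            draw_jackknife_samples(["c1"], ["k1", "k2"], n=2, subset_size=3, seed=0)


def _random_submodel(rng, n=30, d=4, k=5):
    ids = [f"t{i:02d}" for i in range(n)]
    return KnnSubModel(
        sample_ids=ids,
        features=rng.normal(size=(n, d)),
        labels=rng.integers(0, 2, size=n),
        k_neighbors=k,
    )


def brute_force_knn_score(model, query):
    """All-pairs oracle: sort (distance, sample id) pairs and vote."""
    pairs = sorted(
        (float(np.linalg.norm(model.features[i] - query)), model.sample_ids[i], i)
        for i in range(len(model.sample_ids))
    )
    top = pairs[: model.k_neighbors]
    return sum(model.labels[i] for _, _, i in top) / model.k_neighbors


class TestSubmodelScore:
    def test_coincident_with_case_cluster(self):
        features = np.vstack([np.zeros((3, 2)), np.full((4, 2), 10.0)])
        model = KnnSubModel(
            sample_ids=[f"s{i}" for i in range(7)],
            features=features,
            labels=np.array([1, 1, 1, 0, 0, 0, 0]),
            k_neighbors=3,
        )
        assert submodel_score(model, np.zeros(2)) == 1.0
        assert submodel_score(model, np.full(2, 10.0)) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        model = _random_submodel(rng)
        for _ in range(50):
            q = rng.normal(size=4)
            assert submodel_score(model, q) == pytest.approx(
                brute_force_knn_score(model, q), abs=1e-12
            )

    def test_matches_sklearn_on_tie_free_data(self):
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(8)
        model = _random_submodel(rng, n=40, d=3, k=7)
        clf = KNeighborsClassifier(n_neighbors=7).fit(model.features, model.labels)
        queries = rng.normal(size=(20, 3))
        ours = _neighbor_scores(model, queries)
        np.testing.assert_allclose(ours, clf.predict_proba(queries)[:, 1], atol=1e-12)

    def test_dimension_mismatch_is_error(self):
        model = _random_submodel(np.random.default_rng(0))
        with pytest.raises(DataError):
            submodel_score(model, np.zeros(5))


class TestPps:
    def _model_from_submodels(self, rng, n_sub):
        subs = [_random_submodel(rng) for _ in range(n_sub)]
        sig = mt.GeneSignature(
            finding=FINDING,
            gene_ids=[f"g{i}" for i in range(4)],
            p_values=np.sort(rng.uniform(size=4)),
            fraction=0.05,
        )
        return mt.PathologyModel(finding=FINDING, signature=sig, submodels=subs)

    def test_pps_is_mean_of_submodels(self):
        rng = np.random.default_rng(1)
        model = self._model_from_submodels(rng, 7)
        q = rng.normal(size=4)
        expected = np.mean([submodel_score(s, q) for s in model.submodels])
        assert compute_pps(model, q) == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= compute_pps(model, q) <= 1.0

    def test_pps_invariant_to_submodel_order(self):
        rng = np.random.default_rng(2)
        model = self._model_from_submodels(rng, 5)
        q = rng.normal(size=4)
        before = compute_pps(model, q)
        model.submodels.reverse()
        assert compute_pps(model, q) == pytest.approx(before, abs=1e-12)


class TestTraining:
    def _dataset(self, seed=0, n_cases=8, n_controls=40, n_genes=60, shift=2.0):
        rng = np.random.default_rng(seed)
        n = n_cases + n_controls
        values = rng.normal(0, 1, (n, n_genes))
        values[:n_cases, :10] += shift
        expr = mt.ExpressionMatrix(
            [f"s{i:02d}" for i in range(n)],
            [f"g{j:02d}" for j in range(n_genes)],
            values,
        )
        cases = expr.sample_ids[:n_cases]
        controls = expr.sample_ids[n_cases:]
        return expr, cases, controls

    def test_balanced_subsetting_matches_case_count(self):
        expr, cases, controls = self._dataset()
        config = mt.StudyConfig(n_submodels=6, knn_k=3)
        model = train_pathology_model(expr, FINDING, cases, controls, config, seed=1)
        for sub in model.submodels:
            assert len(sub.sample_ids) == 16  # 8 cases + 8 controls
            assert sub.labels.sum() == 8

    def test_single_submodel_pps_equals_submodel_score(self):
        expr, cases, controls = self._dataset()
        config = mt.StudyConfig(n_submodels=1, knn_k=3)
        model = train_pathology_model(expr, FINDING, cases, controls, config, seed=1)
        q = expr.gene_columns(model.signature.gene_ids)[3]
        assert compute_pps(model, q) == submodel_score(model.submodels[0], q)

    def test_held_out_cases_score_above_controls(self):
        expr, cases, controls = self._dataset(seed=3, n_cases=12, n_controls=60)
        config = mt.StudyConfig(n_submodels=10, knn_k=3)
        model = train_pathology_model(
            expr, FINDING, cases[:8], controls[:40], config, seed=2
        )
        held_expr = expr.subset_samples(list(cases[8:]) + list(controls[40:]))
        scores = compute_pps_batch(model, held_expr)
        assert scores[:4].mean() > scores[4:].mean()

    def test_untrainable_without_cases(self):
        expr, _, controls = self._dataset()
        config = mt.StudyConfig()
        with pytest.raises(UntrainableFindingError):
            train_pathology_model(expr, FINDING, [], controls, config, seed=0)
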