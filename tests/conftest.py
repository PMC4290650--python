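import numpy as np
import pytest

import multitox as mt


@pytest.fixture(scope="session")
def small_dataset():
    """A small drug-grouped dataset with planted signal and correlated
    findings, shared by the end-to-end tests."""
    design = mt.SimulationDesign(
        n_drugs=10,
        samples_per_drug=6,
        n_genes=200,
        prevalence_target=0.2,
        effect_size=2.0,
        signature_size=20,
        seed=7,
    )
    return mt.simulate_dataset(design)


@pytest.fixture(scope="session")
def small_config():
    return mt.StudyConfig(
        n_submodels=8, knn_k=3, cv_folds=3, random_seed=7
    )


def make_orthogonal_findings_dataset(seed=11):
    """A dataset whose two findings never co-occur, so every training-fold
    similarity matrix is exactly the identity."""
    rng = np.random.default_rng(seed)
    n_drugs, per_drug, n_genes = 12, 6, 60
    n = n_drugs * per_drug
    sample_ids = [f"s{i:03d}" for i in range(n)]
    drugs = [f"d{i // per_drug:02d}" for i in range(n)]
    organs = ["liver" if i % 2 else "kidney" for i in range(n)]
    values = rng.normal(0, 1, (n, n_genes))
    # disjoint case sets: within every drug, sample 0 presents finding A
    # and sample 1 presents finding B, so each training fold keeps >=2
    # cases of both findings and the supports never intersect
    occ = np.zeros((n, 2), dtype=np.int8)
    occ[np.arange(0, n, per_drug), 0] = 1
    occ[np.arange(1, n, per_drug), 1] = 1
    values[occ[:, 0] == 1, :15] += 2.5
    values[occ[:, 1] == 1, 15:30] += 2.5
    expr = mt.ExpressionMatrix(sample_ids, [f"g{j:03d}" for j in range(n_genes)], values)
    ann = mt.SampleAnnotation(sample_ids, drugs, organs)
    findings = [
        mt.PathologyFinding("liver", "Necrosis"),
        mt.PathologyFinding("kidney", "Dilatation"),
    ]
    occm = mt.PathologyOccurrenceMatrix(sample_ids, findings, occ)
    return expr, ann, occm


@pytest.fixture(scope="session")
def orthogonal_findings_dataset():
    return make_orthogonal_findings_dataset()
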