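"""Individual pathology prediction models.

One finding's model is an ensemble of ``n`` k-nearest-neighbor
sub-models, each fitted on a *jackknife sample*: all confirmed case
samples plus a randomly drawn subset of controls. Undersampling the
controls per sub-model counters the severe class imbalance typical of
adverse-reaction data, while keeping every case in every sub-model.

Each sub-model scores a test profile by the fraction of its k nearest
training points (Euclidean distance on the finding's signature genes)
that are cases, so sub-model outputs live in [0, 1]. The pathology
prediction score (PPS) is their arithmetic mean:

    M_Fi(s) = (1/n) * sum_k sub_M_Fi^k(s)

Values near 1 indicate the finding is likely to present in sample s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import (
    DataError,
    ExpressionMatrix,
    MultitoxError,
    PathologyFinding,
    StudyConfig,
)
from .signature_selection import (
    GeneSignature,
    build_signature,
    read_signature,
    write_signature,
)


class UntrainableFindingError(MultitoxError):
    """Raised when a finding lacks the training samples a model needs."""


@dataclass
class JackknifeSample:
    """One resample: all cases plus a random subset of controls."""

    case_ids: list[str]
    control_ids: list[str]
    seed_used: int

    def __post_init__(self) -> None:
        if len(set(self.control_ids)) != len(self.control_ids):
            raise DataError("jackknife control subset contains duplicates")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.case_ids) + list(self.control_ids)


def draw_jackknife_samples(
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    n: int,
    subset_size: int,
    seed: int,
) -> list[JackknifeSample]:
    """Draw ``n`` jackknife samples, each keeping every case and
    ``subset_size`` controls sampled without replacement, independently
    per resample. Fully reproducible from ``seed``."""
    case_ids = [str(s) for s in case_ids]
    control_ids = [str(s) for s in control_ids]
    if n < 1:
        raise DataError("number of jackknife samples must be >= 1")
    if subset_size > len(control_ids):
        raise DataError(
            f"control subset size {subset_size} exceeds available "
            f"controls ({len(control_ids)})"
        )
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        chosen = rng.choice(len(control_ids), size=subset_size, replace=False)
        out.append(
            JackknifeSample(
                case_ids=list(case_ids),
                control_ids=[control_ids[i] for i in sorted(chosen)],
                seed_used=int(child.generate_state(1)[0]),
            )
        )
    return out


@dataclass
class KnnSubModel:
    """One KNN classifier over signature-restricted feature vectors."""

    sample_ids: list[str]
    features: np.ndarray  # (n_training, n_signature_genes)
    labels: np.ndarray  # binary, 1 = case
    k_neighbors: int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.features.shape[0] != len(self.sample_ids):
            raise DataError("sub-model features misaligned with sample ids")
        if self.labels.shape != (len(self.sample_ids),):
            raise DataError("sub-model labels misaligned with sample ids")
        if self.k_neighbors > len(self.sample_ids):
            raise DataError(
                f"k_neighbors={self.k_neighbors} exceeds training set size "
                f"{len(self.sample_ids)}"
            )
        # rank of each training point's id; used for the deterministic
        # distance tie-break (lower sample id wins).
        self._id_rank = np.argsort(np.argsort(np.asarray(self.sample_ids)))


def _neighbor_scores(model: KnnSubModel, queries: np.ndarray) -> np.ndarray:
    """Fraction of case labels among the k nearest training points for each
    query row. Distance ties at the k-th neighbor are broken toward the
    lexicographically lower sample id."""
    d2 = ((model.features[None, :, :] - queries[:, None, :]) ** 2).sum(axis=2)
    scores = np.empty(queries.shape[0])
    for i in range(queries.shape[0]):
        order = np.lexsort((model._id_rank, d2[i]))
        scores[i] = model.labels[order[: model.k_neighbors]].mean()
    return scores


def submodel_score(model: KnnSubModel, sample_features: np.ndarray) -> float:
    """Score one profile with one sub-model; in [0, 1]."""
    x = np.asarray(sample_features, dtype=float)
    if x.shape != (model.features.shape[1],):
        raise DataError(
            f"feature vector of length {x.shape} does not match signature "
            f"length {model.features.shape[1]}"
        )
    return float(_neighbor_scores(model, x[None, :])[0])


@dataclass
class PathologyModel:
    """One finding's trained ensemble: signature + n KNN sub-models."""

    finding: PathologyFinding
    signature: GeneSignature
    submodels: list[KnnSubModel]

    def __post_init__(self) -> None:
        if len(self.submodels) < 1:
            raise UntrainableFindingError(
                f"model for {self.finding.label} has no sub-models"
            )

    @property
    def n_submodels(self) -> int:
        return len(self.submodels)


def compute_pps(model: PathologyModel, sample_features: np.ndarray) -> float:
    """Pathology prediction score: mean of the n sub-model outputs."""
    return float(
        np.mean([submodel_score(sub, sample_features) for sub in model.submodels])
    )


def compute_pps_batch(model: PathologyModel, expr: ExpressionMatrix) -> np.ndarray:
    """PPS for every sample in ``expr`` (restricted to signature genes)."""
    queries = expr.gene_columns(model.signature.gene_ids)
    scores = np.zeros(expr.n_samples)
    for sub in model.submodels:
        scores += _neighbor_scores(sub, queries)
    return scores / model.n_submodels


def resolve_subset_size(config: StudyConfig, n_cases: int) -> int:
    if config.control_subset_size == "balanced":
        return n_cases
    return int(config.control_subset_size)


def train_pathology_model(
    expr: ExpressionMatrix,
    finding: PathologyFinding,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    config: StudyConfig,
    seed: int,
) -> PathologyModel:
    """Fit one finding's ensemble on the given training samples.

    The gene signature is selected on the *same* training samples the
    sub-models are fitted on, so no information from held-out data leaks
    into feature selection.
    """
    case_ids = [str(s) for s in case_ids]
    control_ids = [str(s) for s in control_ids]
    if len(case_ids) == 0:
        raise UntrainableFindingError(
            f"finding {finding.label} untrainable: no case samples"
        )
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise UntrainableFindingError(
            f"finding {finding.label} untrainable: needs >=2 cases and "
            f">=2 controls, got {len(case_ids)}/{len(control_ids)}"
        )
    subset_size = resolve_subset_size(config, len(case_ids))
    if subset_size > len(control_ids):
        raise UntrainableFindingError(
            f"finding {finding.label} untrainable: control subset size "
            f"{subset_size} exceeds available controls ({len(control_ids)})"
        )
    signature = build_signature(
        expr, finding, case_ids, control_ids, config.signature_fraction
    )
    jackknives = draw_jackknife_samples(
        case_ids, control_ids, config.n_submodels, subset_size, seed
    )
    submodels = []
    for jk in jackknives:
        ids = jk.sample_ids
        sub_expr = expr.subset_samples(ids)
        features = sub_expr.gene_columns(signature.gene_ids)
        labels = np.array(
            [1] * len(jk.case_ids) + [0] * len(jk.control_ids), dtype=np.int8
        )
        k = min(config.knn_k, len(ids))
        submodels.append(
            KnnSubModel(
                sample_ids=ids, features=features, labels=labels, k_neighbors=k
            )
        )
    return PathologyModel(finding=finding, signature=signature, submodels=submodels)


# ---------------------------------------------------------------------------
# Persistence: a model directory holds the signature TSV, per-sub-model
# training-id lists, and a config snapshot; prediction re-reads features
# from the training expression matrix.


def save_model(directory: str | Path, model: PathologyModel, config: StudyConfig) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_signature(directory / "signature.tsv", model.signature)
    meta = {
        "finding": model.finding.label,
        "signature_fraction": model.signature.fraction,
        "config": config.to_dict(),
        "submodels": [
            {
                "sample_ids": sub.sample_ids,
                "labels": sub.labels.tolist(),
                "k_neighbors": sub.k_neighbors,
            }
            for sub in model.submodels
        ],
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(directory: str | Path, training_expr: ExpressionMatrix) -> PathologyModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    finding = PathologyFinding.from_label(meta["finding"])
    signature = read_signature(
        directory / "signature.tsv", finding, meta["signature_fraction"]
    )
    submodels = []
    for sub in meta["submodels"]:
        features = training_expr.subset_samples(sub["sample_ids"]).gene_columns(
            signature.gene_ids
        )
        submodels.append(
            KnnSubModel(
                sample_ids=sub["sample_ids"],
                features=features,
                labels=np.asarray(sub["labels"], dtype=np.int8),
                k_neighbors=sub["k_neighbors"],
            )
        )
    return PathologyModel(finding=finding, signature=signature, submodels=submodels)
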