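"""Pathology co-occurrence similarities and their row normalization.

Two findings that tend to present in the same training samples are
related — a toxic perturbation of shared pathways produces multiple
symptoms — and that relatedness is measured by the Jaccard coefficient of
their binary occurrence vectors:

    S(Fi, Fj) = N11 / (N01 + N10 + N11)

where N11 counts samples presenting both findings and N01/N10 count
samples presenting exactly one. Co-absence (N00) never enters. The k x k
similarity matrix S is then row-normalized into the integration weights
N(Fi, Fj); under the default ``l2`` scheme each row of S is divided by
its Euclidean norm, so every nonzero row of N has unit length:

    N(Fi, Fj) = S(Fi, Fj) / sqrt(sum_m S(Fi, Fm)^2)

The ``sum_sq`` scheme divides by the plain sum of squares instead (no
square root) and is kept for sensitivity analysis. Note N is generally
NOT symmetric even though S is, because normalization is row-wise.

During cross-validation, S and N must be computed from training-fold
samples only; that restriction is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    DataError,
    PathologyFinding,
    PathologyOccurrenceMatrix,
)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise Jaccard similarities between findings."""

    findings: list[PathologyFinding]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.findings)
        if self.values.shape != (k, k):
            raise DataError(f"similarity matrix shape {self.values.shape} != ({k}, {k})")
        if not np.allclose(self.values, self.values.T):
            raise DataError("similarity matrix must be symmetric")
        if (self.values < 0).any() or (self.values > 1).any():
            raise DataError("similarity values must lie in [0, 1]")


@dataclass
class NormalizedSimilarityMatrix:
    """Row-normalized similarities: the weights of the integrative model."""

    findings: list[PathologyFinding]
    values: np.ndarray
    scheme: str = "l2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.findings)
        if self.values.shape != (k, k):
            raise DataError(
                f"normalized similarity shape {self.values.shape} != ({k}, {k})"
            )
        if (self.values < 0).any():
            raise DataError("normalized similarities must be nonnegative")


def jaccard_similarity(phi_i: np.ndarray, phi_j: np.ndarray) -> float:
    """Jaccard coefficient of two binary occurrence vectors.

    Two all-zero vectors share no occurrences; the empty-union case 0/0 is
    defined as 0.
    """
    a = np.asarray(phi_i)
    b = np.asarray(phi_j)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError(
            f"occurrence vectors have mismatched shapes {a.shape} vs {b.shape}"
        )
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise DataError("occurrence vectors must be binary")
    a = a.astype(bool)
    b = b.astype(bool)
    n11 = int((a & b).sum())
    union = int((a | b).sum())  # = N01 + N10 + N11
    if union == 0:
        return 0.0
    return n11 / union


def build_similarity_matrix(occ: PathologyOccurrenceMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard similarities between all finding columns of the
    occurrence matrix.

    The diagonal is fixed at 1 even for a finding never observed in these
    samples, so such a finding degrades gracefully to its own prediction
    score downstream instead of being zeroed out.
    """
    if occ.n_findings < 1:
        raise DataError("occurrence matrix has no findings")
    phi = occ.values.astype(np.int64)
    inter = phi.T @ phi
    counts = phi.sum(axis=0)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(findings=list(occ.findings), values=s)


def normalize_similarity(
    s: SimilarityMatrix, scheme: str = "l2"
) -> NormalizedSimilarityMatrix:
    """Row-normalize a similarity matrix into integration weights."""
    if scheme not in ("l2", "sum_sq"):
        raise DataError(f"unknown normalization scheme {scheme!r}")
    sq = (s.values**2).sum(axis=1)
    if (sq == 0).any():
        bad = s.findings[int(np.argmax(sq == 0))]
        raise DataError(
            f"similarity row for {bad.label} is all zero and cannot be normalized"
        )
    denom = np.sqrt(sq) if scheme == "l2" else sq
    return NormalizedSimilarityMatrix(
        findings=list(s.findings), values=s.values / denom[:, None], scheme=scheme
    )


def write_similarity(
    path: str | Path, matrix: SimilarityMatrix | NormalizedSimilarityMatrix
) -> None:
    labels = [f.label for f in matrix.findings]
    df = pd.DataFrame(matrix.values, index=labels, columns=labels)
    df.index.name = "finding"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    findings = [PathologyFinding.from_label(c) for c in df.columns]
    return SimilarityMatrix(findings=findings, values=df.to_numpy(dtype=float))
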