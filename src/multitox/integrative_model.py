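"""The integrative prediction score (IPS).

Individual pathology prediction scores are combined across findings with
the normalized co-occurrence similarities as weights:

    IPS_Fi(s) = sum_m N(Fi, Fm) * M_Fm(s)

i.e. the IPS vector is the matrix-vector product N . M(s). A finding's
IPS thus borrows evidence from findings it frequently co-occurs with: a
high score from a strongly associated finding pulls the IPS up, a low one
pulls it down. The sum runs over all k findings including Fi itself
(whose self-weight is the largest entry of its row under l2
normalization).

IPS values are not clipped to [0, 1]; decision thresholds are tuned on
the IPS scale directly, and a finding is called present when its score is
strictly greater than its threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import DataError, PathologyFinding
from .pathology_relationships import NormalizedSimilarityMatrix


@dataclass
class PpsVector:
    """Per-finding pathology prediction scores for one sample."""

    findings: list[PathologyFinding]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.findings),):
            raise DataError("PPS vector misaligned with findings")
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise DataError("PPS values must lie in [0, 1]")


@dataclass
class IpsVector:
    """Per-finding integrative prediction scores for one sample."""

    findings: list[PathologyFinding]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.findings),):
            raise DataError("IPS vector misaligned with findings")
        if (self.scores < 0).any():
            raise DataError("IPS values must be nonnegative")


def compute_ips(n: NormalizedSimilarityMatrix, pps: PpsVector) -> IpsVector:
    """Similarity-weighted combination of all findings' PPS values.

    The finding order of the weight matrix and the score vector must be
    identical; mismatches are an error, never silently reordered.
    """
    if [f.label for f in n.findings] != [f.label for f in pps.findings]:
        raise DataError(
            "finding order mismatch between normalized similarity matrix and "
            "PPS vector"
        )
    return IpsVector(findings=list(pps.findings), scores=n.values @ pps.scores)


def compute_ips_matrix(
    n: NormalizedSimilarityMatrix, pps_matrix: np.ndarray
) -> np.ndarray:
    """IPS for many samples at once: rows are samples, columns findings."""
    pps_matrix = np.asarray(pps_matrix, dtype=float)
    if pps_matrix.shape[1] != len(n.findings):
        raise DataError("PPS matrix column count does not match findings")
    return pps_matrix @ n.values.T


def predict_findings(
    ips: IpsVector, thresholds: Mapping[str, float] | Sequence[float]
) -> np.ndarray:
    """Binary presence calls: 1 iff IPS is strictly greater than the
    finding's threshold (boundary equality is called absent)."""
    if isinstance(thresholds, Mapping):
        try:
            thr = np.array([thresholds[f.label] for f in ips.findings], dtype=float)
        except KeyError as exc:
            raise DataError(f"missing threshold for finding {exc.args[0]!r}") from None
    else:
        thr = np.asarray(thresholds, dtype=float)
        if thr.shape != (len(ips.findings),):
            raise DataError("threshold vector misaligned with findings")
    return (ips.scores > thr).astype(np.int8)
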