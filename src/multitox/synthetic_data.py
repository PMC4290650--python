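"""Synthetic drug-grouped toxicogenomics datasets.

The generator emulates the structure the prediction pipeline relies on,
without any external database: samples grouped by administered compound,
rare findings (imbalanced case/control columns), correlated finding
co-occurrence, and planted differential-expression signatures.

The mechanism is causal rather than a direct draw of the occurrence
matrix: each drug activates a subset of latent *toxicity mechanisms*
(perturbed pathway bundles); a sample's mechanism activity is its drug's
activation plus sample-level noise; a finding occurs when its
loading-weighted activity exceeds a cutoff calibrated from the empirical
latent distribution so the requested prevalence is honored regardless of
loading scale. Findings loading on shared mechanisms therefore co-occur
(nonzero Jaccard similarity), and every occurring finding shifts its own
disjoint block of signature genes by ``effect_size`` noise-standard
-deviations on top of i.i.d. Gaussian background expression — toxic
perturbations leave both a symptom and a transcriptional trace, the
premise the integrative model exploits.

Everything is reproducible bit-for-bit from ``design.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import (
    DataError,
    ExpressionMatrix,
    PathologyFinding,
    PathologyOccurrenceMatrix,
    SampleAnnotation,
)


def _default_findings() -> list[PathologyFinding]:
    return [
        PathologyFinding("liver", "Necrosis"),
        PathologyFinding("liver", "Cellular infiltration"),
        PathologyFinding("liver", "Hypertrophy"),
        PathologyFinding("liver", "Single cell necrosis"),
        PathologyFinding("kidney", "Regeneration"),
        PathologyFinding("kidney", "Vacuolization, cytoplasmic"),
    ]


@dataclass
class SimulationDesign:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale study: 20 compounds with 10 profiled
    samples each, 400 genes, 6 findings across liver and kidney driven by
    3 latent mechanisms, 15% prevalence per finding, planted signatures
    of 20 genes shifted by 1.5 noise-sd in affected samples.
    """

    n_drugs: int = 20
    samples_per_drug: int = 10
    n_genes: int = 400
    findings: list[PathologyFinding] = field(default_factory=_default_findings)
    mechanisms: int = 3
    loading: np.ndarray | None = None  # findings x mechanisms, nonnegative
    drug_activation: np.ndarray | None = None  # drugs x mechanisms
    activation_prob: float = 0.3  # used when drug_activation is generated
    prevalence_target: float | Sequence[float] = 0.15
    effect_size: float | Sequence[float] = 1.5
    signature_size: int = 20
    signature_overlap: float = 0.0  # fraction of each block shared with the next
    background_noise_sd: float = 1.0
    mechanism_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.findings)
        if self.n_drugs < 2 or self.samples_per_drug < 1 or self.n_genes < 1:
            raise DataError("design sizes must be positive (and >=2 drugs)")
        if self.mechanisms < 1 or k < 1:
            raise DataError("need at least one mechanism and one finding")
        self.prevalence = np.broadcast_to(
            np.asarray(self.prevalence_target, dtype=float), (k,)
        ).copy()
        if ((self.prevalence <= 0) | (self.prevalence >= 1)).any():
            raise DataError("prevalence_target must lie in (0, 1)")
        self.effects = np.broadcast_to(
            np.asarray(self.effect_size, dtype=float), (k,)
        ).copy()
        if (self.effects < 0).any():
            raise DataError("effect_size must be nonnegative")
        if self.loading is not None:
            self.loading = np.asarray(self.loading, dtype=float)
            if self.loading.shape != (k, self.mechanisms):
                raise DataError(
                    f"loading shape {self.loading.shape} != ({k}, {self.mechanisms})"
                )
            if (self.loading < 0).any():
                raise DataError("loading must be nonnegative")
        if self.drug_activation is not None:
            self.drug_activation = np.asarray(self.drug_activation, dtype=float)
            if self.drug_activation.shape != (self.n_drugs, self.mechanisms):
                raise DataError(
                    f"drug_activation shape {self.drug_activation.shape} != "
                    f"({self.n_drugs}, {self.mechanisms})"
                )
        if not 0 <= self.signature_overlap < 1:
            raise DataError("signature_overlap must lie in [0, 1)")
        step = max(1, round(self.signature_size * (1 - self.signature_overlap)))
        span = (k - 1) * step + self.signature_size
        if span > self.n_genes:
            raise DataError(
                f"signature blocks need {span} genes but only "
                f"{self.n_genes} are available"
            )

    @property
    def n_samples(self) -> int:
        return self.n_drugs * self.samples_per_drug

    def signature_block(self, finding_index: int) -> np.ndarray:
        """Gene column indices planted for one finding (disjoint blocks by
        default; consecutive blocks share ``signature_overlap`` of their
        genes when requested)."""
        step = max(1, round(self.signature_size * (1 - self.signature_overlap)))
        start = finding_index * step
        return np.arange(start, start + self.signature_size)


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[ExpressionMatrix, SampleAnnotation, PathologyOccurrenceMatrix]:
    """Draw one dataset from the design's generative model."""
    rng = np.random.default_rng(design.seed)
    k = len(design.findings)
    n = design.n_samples

    loading = design.loading
    if loading is None:
        # round-robin: each finding loads 1.0 on one mechanism
        loading = np.zeros((k, design.mechanisms))
        for j in range(k):
            loading[j, j % design.mechanisms] = 1.0

    activation = design.drug_activation
    if activation is None:
        activation = rng.binomial(
            1, design.activation_prob, size=(design.n_drugs, design.mechanisms)
        ).astype(float)
        # every mechanism must be reachable by at least one drug
        for m in range(design.mechanisms):
            if activation[:, m].sum() == 0:
                activation[rng.integers(design.n_drugs), m] = 1.0

    drug_ids = [f"drug{d + 1:03d}" for d in range(design.n_drugs)]
    sample_ids = [f"s{i + 1:05d}" for i in range(n)]
    sample_drug_index = np.repeat(np.arange(design.n_drugs), design.samples_per_drug)

    activity = activation[sample_drug_index] + rng.normal(
        0.0, design.mechanism_noise_sd, size=(n, design.mechanisms)
    )
    latent = activity @ loading.T  # samples x findings

    occ_values = np.zeros((n, k), dtype=np.int8)
    for j in range(k):
        cutoff = np.quantile(latent[:, j], 1 - design.prevalence[j])
        occ_values[:, j] = latent[:, j] > cutoff

    expr_values = rng.normal(0.0, design.background_noise_sd, size=(n, design.n_genes))
    for j in range(k):
        block = design.signature_block(j)
        cases = occ_values[:, j] == 1
        expr_values[np.ix_(cases, block)] += (
            design.effects[j] * design.background_noise_sd
        )

    # half of each drug's samples profiled in liver, half in kidney
    organs = [
        "liver" if (i % design.samples_per_drug) < design.samples_per_drug / 2
        else "kidney"
        for i in range(n)
    ]
    gene_ids = [f"g{j + 1:05d}" for j in range(design.n_genes)]
    expr = ExpressionMatrix(sample_ids, gene_ids, expr_values)
    ann = SampleAnnotation(
        sample_ids, [drug_ids[d] for d in sample_drug_index], organs
    )
    occ = PathologyOccurrenceMatrix(sample_ids, list(design.findings), occ_values)
    return expr, ann, occ


def empirical_prevalence(occ: PathologyOccurrenceMatrix) -> np.ndarray:
    """Per-finding case fraction: the column means of the occurrence
    matrix."""
    if occ.n_samples == 0:
        raise DataError("occurrence matrix is empty")
    return occ.values.mean(axis=0)


def imbalanced_codependent_design(seed: int = 0) -> SimulationDesign:
    """A regime where integration should help: one rare, weak-signal
    finding that strongly co-occurs with two well-predicted findings.

    The rare finding (prevalence 2%, about 1:49 imbalance) and the two
    strong findings load on the same mechanism, so its few cases are a
    subset of the strong findings' cases — Jaccard similarity 0.5 — while
    its own expression shift (0.5 sd on 15 genes) is faint. Over a
    genome-scale universe of 5000 genes, a top-5% signature selected from
    3-4 training cases is dominated by noise genes (a handful of lucky
    p-values out-rank the genuinely shifted genes at such low degrees of
    freedom), so the rare finding's own KNN ensemble degrades — the
    instability that severe imbalance causes in practice — whereas the
    strong findings (effect 2 sd) keep clean signatures and reliable
    scores that integration can borrow. Two background findings on a
    second mechanism keep the similarity matrix non-trivial.
    """
    findings = [
        PathologyFinding("liver", "Single cell necrosis"),  # weak, rare
        PathologyFinding("liver", "Necrosis"),  # strong
        PathologyFinding("liver", "Cellular infiltration"),  # strong
        PathologyFinding("kidney", "Regeneration"),  # background
        PathologyFinding("kidney", "Cast, hyaline"),  # background
    ]
    loading = np.array(
        [
            [1.0, 0.0],
            [1.0, 0.0],
            [1.0, 0.0],
            [0.0, 1.0],
            [0.0, 1.0],
        ]
    )
    return SimulationDesign(
        n_drugs=25,
        samples_per_drug=8,
        n_genes=5000,
        findings=findings,
        mechanisms=2,
        loading=loading,
        activation_prob=0.3,
        prevalence_target=[0.02, 0.04, 0.04, 0.15, 0.15],
        effect_size=[0.5, 2.0, 2.0, 1.0, 1.0],
        signature_size=15,
        background_noise_sd=1.0,
        mechanism_noise_sd=0.5,
        seed=seed,
    )
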