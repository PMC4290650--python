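"""Drug-grouped cross-validation of individual and integrative models.

Samples exposed to the same compound are highly correlated, so folds are
formed *in the unit of drugs*: every sample of a drug lands in the same
fold, and no compound ever appears on both sides of a split. Within each
fold, everything that can leak — gene signatures, pathology models, the
co-occurrence similarity matrix S and its normalization N — is refit on
the training drugs only.

Decision thresholds are chosen to maximize the geometric mean of
sensitivity and specificity, sqrt(sens * spec), the customary operating
point for imbalanced classes. Thresholds are tuned on training-fold
scores (tuning on test predictions would be leakage) and applied to the
held-out samples with a strict ``>`` call. Ranking quality is summarized
by the rank-based (Mann-Whitney) AUC with half credit for score ties.

Metrics are pooled over test folds (micro-average); a per-fold breakdown
is also retained so macro-averages can be computed from the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    DataError,
    ExpressionMatrix,
    PathologyFinding,
    PathologyOccurrenceMatrix,
    SampleAnnotation,
    StudyConfig,
    filter_findings,
)
from .integrative_model import compute_ips_matrix
from .pathology_model import (
    UntrainableFindingError,
    compute_pps_batch,
    train_pathology_model,
)
from .pathology_relationships import build_similarity_matrix, normalize_similarity

logger = logging.getLogger(__name__)

SCORERS = ("PPS", "IPS")


@dataclass
class FoldAssignment:
    """Mapping of each drug to its cross-validation fold."""

    assignment: dict[str, int]
    n_folds: int

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if folds - set(range(self.n_folds)):
            raise DataError("fold indices out of range")
        sizes = self.fold_sizes()
        if max(sizes) - min(sizes) > 1:
            raise DataError("fold drug-counts differ by more than 1")

    def fold_of(self, drug: str) -> int:
        try:
            return self.assignment[drug]
        except KeyError:
            raise DataError(f"drug {drug!r} has no fold assignment") from None

    def drugs_in_fold(self, fold: int) -> list[str]:
        return sorted(d for d, f in self.assignment.items() if f == fold)

    def fold_sizes(self) -> list[int]:
        return [len(self.drugs_in_fold(f)) for f in range(self.n_folds)]


def make_drug_folds(
    drugs: Sequence[str], n_folds: int, seed: int
) -> FoldAssignment:
    """Random balanced partition of the distinct drugs into folds (sizes
    differ by at most one)."""
    unique = sorted(set(str(d) for d in drugs))
    if n_folds > len(unique):
        raise DataError(
            f"cannot split {len(unique)} drugs into {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    assignment = {unique[j]: i % n_folds for i, j in enumerate(order)}
    return FoldAssignment(assignment=assignment, n_folds=n_folds)


# ---------------------------------------------------------------------------
# Threshold selection and metrics


def sensitivity_specificity(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    """Sensitivity and specificity of the strict-``>`` call at a threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    calls = scores > threshold
    pos = labels == 1
    neg = ~pos
    sens = float(calls[pos].mean()) if pos.any() else float("nan")
    spec = float((~calls[neg]).mean()) if neg.any() else float("nan")
    return sens, spec


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def choose_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing the geometric mean of sensitivity and
    specificity.

    Candidates are the midpoints between consecutive distinct scores plus
    one candidate below the minimum and one above the maximum. Ties in
    the geometric mean are broken toward the lowest threshold (favoring
    sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise DataError("threshold selection needs both classes present")
    best_thr = None
    best_gmean = -1.0
    for thr in _candidate_thresholds(scores):
        sens, spec = sensitivity_specificity(scores, labels, thr)
        gmean = np.sqrt(sens * spec)
        if gmean > best_gmean:
            best_gmean = gmean
            best_thr = thr
    return float(best_thr)


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with 0.5 credit for tied scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) coordinates of the strict-``>`` ROC curve, from (0, 0)
    to (1, 1), one point per distinct score."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tps = np.cumsum(pos[order])
    fps = np.cumsum(~pos[order])
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


# ---------------------------------------------------------------------------
# Cross-validation driver


@dataclass
class ScorerMetrics:
    sensitivity: float
    specificity: float
    auc: float
    threshold: float  # mean of per-fold tuned thresholds


@dataclass
class FoldMetrics:
    fold: int
    scorer: str
    finding: str
    sensitivity: float
    specificity: float
    auc: float
    threshold: float
    n_test_cases: int
    n_test_controls: int


@dataclass
class FoldDetail:
    """Per-fold refit artifacts, kept so leakage audits can verify that
    signatures, models and similarities differ across folds."""

    fold: int
    train_drugs: list[str]
    test_drugs: list[str]
    trained_findings: list[str]
    signatures: dict[str, tuple[str, ...]]
    similarity: np.ndarray
    thresholds: dict[tuple[str, str], float]  # (scorer, finding) -> threshold


@dataclass
class FindingEvaluation:
    finding: PathologyFinding
    metrics: dict[str, ScorerMetrics]
    n_cases: int
    n_controls: int


@dataclass
class EvaluationReport:
    findings: list[FindingEvaluation]
    per_fold: list[FoldMetrics]
    fold_details: list[FoldDetail]
    fold_assignment: FoldAssignment
    skipped: list[tuple[int, str, str]]  # (fold, finding, reason)
    config: StudyConfig

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for fe in self.findings:
            for scorer, m in fe.metrics.items():
                rows.append(
                    {
                        "finding": fe.finding.label,
                        "scorer": scorer,
                        "sensitivity": m.sensitivity,
                        "specificity": m.specificity,
                        "auc": m.auc,
                        "threshold": m.threshold,
                        "n_cases": fe.n_cases,
                        "n_controls": fe.n_controls,
                    }
                )
        return pd.DataFrame(rows)

    def per_fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.per_fold])

    def auc(self, finding_label: str, scorer: str) -> float:
        for fe in self.findings:
            if fe.finding.label == finding_label:
                return fe.metrics[scorer].auc
        raise DataError(f"finding {finding_label!r} not in report")


def _model_seed(master: int, fold: int, finding_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=(fold, finding_index))


def run_cross_validation(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    occ: PathologyOccurrenceMatrix,
    config: StudyConfig,
    collect_scores: bool = False,
) -> EvaluationReport:
    """Evaluate individual (PPS) and integrative (IPS) models with
    drug-grouped k-fold cross-validation.

    Per fold, signatures, pathology models, the similarity matrix S and
    its normalization N are fitted on the training drugs only; held-out
    samples receive PPS and IPS scores; thresholds are tuned on the
    training-fold scores. Findings with too few training cases in a fold
    are skipped there with a logged warning. With ``collect_scores=True``
    the pooled per-finding test scores and labels are attached to the
    report as ``report.pooled_scores`` for ROC export.
    """
    if set(expr.sample_ids) != set(ann.sample_ids):
        raise DataError("expression and annotation sample ids do not align")
    if set(expr.sample_ids) != set(occ.sample_ids):
        raise DataError("expression and occurrence sample ids do not align")
    occ = occ.subset_samples(expr.sample_ids)
    if config.min_drugs_per_finding > 0:
        occ = filter_findings(occ, ann, config.min_drugs_per_finding)
    if occ.n_findings == 0:
        raise DataError("no findings left to evaluate")

    sample_drugs = np.asarray(ann.drugs_of(expr.sample_ids))
    fold_seed = np.random.SeedSequence(
        entropy=config.random_seed, spawn_key=(0xF01D,)
    ).generate_state(1)[0]
    folds = make_drug_folds(sample_drugs, config.cv_folds, int(fold_seed))

    labels_all = occ.values  # aligned to expr.sample_ids
    sample_ids = np.asarray(expr.sample_ids)
    k_all = occ.n_findings

    # pooled per-finding accumulators
    pooled_scores: dict[tuple[str, str], list[np.ndarray]] = {}
    pooled_labels: dict[str, list[np.ndarray]] = {f.label: [] for f in occ.findings}
    pooled_calls: dict[tuple[str, str], list[np.ndarray]] = {}
    fold_thresholds: dict[tuple[str, str], list[float]] = {}
    per_fold_metrics: list[FoldMetrics] = []
    fold_details: list[FoldDetail] = []
    skipped: list[tuple[int, str, str]] = []
    tested_once = np.zeros(expr.n_samples, dtype=int)

    for fold in range(config.cv_folds):
        test_drugs = set(folds.drugs_in_fold(fold))
        test_mask = np.isin(sample_drugs, list(test_drugs))
        train_mask = ~test_mask
        assert not (set(sample_drugs[train_mask]) & set(sample_drugs[test_mask])), (
            "drug leakage across the fold split"
        )
        tested_once += test_mask.astype(int)
        train_ids = list(sample_ids[train_mask])
        test_ids = list(sample_ids[test_mask])
        train_expr = expr.subset_samples(train_ids)
        test_expr = expr.subset_samples(test_ids)
        train_occ = occ.subset_samples(train_ids)

        # fit one pathology model per trainable finding
        models = {}
        for j, finding in enumerate(occ.findings):
            col = train_occ.values[:, j]
            case_ids = [train_ids[i] for i in np.flatnonzero(col == 1)]
            control_ids = [train_ids[i] for i in np.flatnonzero(col == 0)]
            seed = int(_model_seed(config.random_seed, fold, j).generate_state(1)[0])
            try:
                models[finding.label] = train_pathology_model(
                    train_expr, finding, case_ids, control_ids, config, seed
                )
            except UntrainableFindingError as exc:
                logger.warning("fold %d: skipping %s (%s)", fold, finding.label, exc)
                skipped.append((fold, finding.label, str(exc)))
        if not models:
            logger.warning("fold %d: no trainable findings", fold)
            continue
        trained = [f for f in occ.findings if f.label in models]
        trained_idx = [occ.findings.index(f) for f in trained]
        for j, finding in zip(trained_idx, trained):
            n_case = int(labels_all[train_mask, j].sum())
            logger.info(
                "fold %d: %s trained with %d cases / %d controls",
                fold,
                finding.label,
                n_case,
                int(train_mask.sum()) - n_case,
            )

        # similarity on training-fold occurrences of the trained findings
        s = build_similarity_matrix(
            PathologyOccurrenceMatrix(
                train_ids, trained, train_occ.values[:, trained_idx]
            )
        )
        n = normalize_similarity(s, config.normalization_scheme)

        # scores: samples x trained findings
        pps_train = np.column_stack(
            [compute_pps_batch(models[f.label], train_expr) for f in trained]
        )
        pps_test = np.column_stack(
            [compute_pps_batch(models[f.label], test_expr) for f in trained]
        )
        ips_train = compute_ips_matrix(n, pps_train)
        ips_test = compute_ips_matrix(n, pps_test)

        detail = FoldDetail(
            fold=fold,
            train_drugs=sorted(set(sample_drugs[train_mask])),
            test_drugs=sorted(test_drugs),
            trained_findings=[f.label for f in trained],
            signatures={
                f.label: tuple(models[f.label].signature.gene_ids) for f in trained
            },
            similarity=s.values.copy(),
            thresholds={},
        )

        for col, (j, finding) in enumerate(zip(trained_idx, trained)):
            y_train = labels_all[train_mask, j]
            y_test = labels_all[test_mask, j]
            pooled_labels[finding.label].append(y_test)
            for scorer, train_scores, test_scores in (
                ("PPS", pps_train[:, col], pps_test[:, col]),
                ("IPS", ips_train[:, col], ips_test[:, col]),
            ):
                thr = choose_threshold(train_scores, y_train)
                key = (scorer, finding.label)
                detail.thresholds[key] = thr
                pooled_scores.setdefault(key, []).append(test_scores)
                pooled_calls.setdefault(key, []).append(
                    (test_scores > thr).astype(np.int8)
                )
                fold_thresholds.setdefault(key, []).append(thr)
                if 0 < y_test.sum() < y_test.size:
                    sens, spec = sensitivity_specificity(test_scores, y_test, thr)
                    per_fold_metrics.append(
                        FoldMetrics(
                            fold=fold,
                            scorer=scorer,
                            finding=finding.label,
                            sensitivity=sens,
                            specificity=spec,
                            auc=compute_auc(test_scores, y_test),
                            threshold=thr,
                            n_test_cases=int(y_test.sum()),
                            n_test_controls=int(y_test.size - y_test.sum()),
                        )
                    )
        fold_details.append(detail)

    if not (tested_once == 1).all():
        raise DataError("internal error: test folds do not cover each sample once")

    findings_eval: list[FindingEvaluation] = []
    scores_export: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for j, finding in enumerate(occ.findings):
        label = finding.label
        if not pooled_labels[label] or ("PPS", label) not in pooled_scores:
            continue
        # labels were pooled only over folds where the finding was trained
        y = np.concatenate(pooled_labels[label])
        metrics = {}
        for scorer in SCORERS:
            key = (scorer, label)
            sc = np.concatenate(pooled_scores[key])
            calls = np.concatenate(pooled_calls[key])
            pos = y == 1
            sens = float(calls[pos].mean()) if pos.any() else float("nan")
            spec = float(1 - calls[~pos].mean()) if (~pos).any() else float("nan")
            auc = (
                compute_auc(sc, y) if 0 < pos.sum() < y.size else float("nan")
            )
            metrics[scorer] = ScorerMetrics(
                sensitivity=sens,
                specificity=spec,
                auc=auc,
                threshold=float(np.mean(fold_thresholds[key])),
            )
            scores_export[key] = (sc, y)
        findings_eval.append(
            FindingEvaluation(
                finding=finding,
                metrics=metrics,
                n_cases=int(labels_all[:, j].sum()),
                n_controls=int(labels_all.shape[0] - labels_all[:, j].sum()),
            )
        )

    report = EvaluationReport(
        findings=findings_eval,
        per_fold=per_fold_metrics,
        fold_details=fold_details,
        fold_assignment=folds,
        skipped=skipped,
        config=config,
    )
    if collect_scores:
        report.pooled_scores = scores_export  # type: ignore[attr-defined]
    return report


def write_report(directory: str | Path, report: EvaluationReport) -> None:
    """Write the pooled metrics, the per-fold breakdown and, when the
    report carries pooled scores, per-finding ROC coordinate tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.metrics_frame().to_csv(directory / "report.tsv", sep="\t", index=False)
    report.per_fold_frame().to_csv(directory / "per_fold.tsv", sep="\t", index=False)
    if report.skipped:
        pd.DataFrame(
            report.skipped, columns=["fold", "finding", "reason"]
        ).to_csv(directory / "skipped.tsv", sep="\t", index=False)
    pooled = getattr(report, "pooled_scores", None)
    if pooled:
        roc_dir = directory / "roc"
        roc_dir.mkdir(exist_ok=True)
        for (scorer, label), (sc, y) in pooled.items():
            if 0 < (y == 1).sum() < y.size:
                fpr, tpr = roc_curve_points(sc, y)
                safe = label.replace(":", "_").replace(" ", "_").replace(",", "")
                pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                    roc_dir / f"{safe}.{scorer}.tsv", sep="\t", index=False
                )
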