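"""Per-finding gene signature selection by t-test ranking.

For each pathological finding, genes are ranked by a two-sample t-test
between confirmed case and control training samples, and the top fraction
(default 5%) with the smallest p-values forms the finding's signature.
Welch's unequal-variance test is the default because case/control group
sizes are typically very unbalanced here; the pooled-variance Student
variant is available behind a flag. No multiple-testing correction is
applied: ranking by raw p-values is all the selection needs.

Signatures must be recomputed inside every cross-validation training fold,
never on the full dataset — the evaluation layer enforces this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, ExpressionMatrix, PathologyFinding


@dataclass
class GeneSignature:
    """Genes discriminating one finding's cases from controls, ordered by
    increasing p-value."""

    finding: PathologyFinding
    gene_ids: list[str]
    p_values: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.gene_ids) != len(self.p_values):
            raise DataError("signature gene_ids and p_values are misaligned")
        if np.any(np.diff(self.p_values) < 0):
            raise DataError("signature p_values must be sorted non-decreasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


def t_test_per_gene(
    expr: ExpressionMatrix,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    equal_var: bool = False,
    return_statistics: bool = False,
):
    """Two-sided two-sample t-test for every gene, cases vs controls.

    Returns one p-value per gene in the matrix's gene order. A gene with
    zero variance in both groups and equal means carries no signal and
    gets p = 1 (its statistic is 0). With ``return_statistics=True`` the
    t statistics are returned alongside (zero where undefined).
    """
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    overlap = set(case_ids) & set(control_ids)
    if overlap:
        raise DataError(f"case and control groups overlap: {sorted(overlap)[:5]}")
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise DataError(
            f"t-test needs >=2 samples per group, got {len(case_ids)} cases "
            f"and {len(control_ids)} controls"
        )
    cases = expr.sample_rows(case_ids)
    controls = expr.sample_rows(control_ids)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(cases, controls, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # 0/0 statistic: no variance in either group and identical means.
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    if return_statistics:
        return p, t
    return p


def signature_size(fraction: float, n_genes: int) -> int:
    """Number of genes in a top-``fraction`` signature: ceil(fraction * n)."""
    return math.ceil(fraction * n_genes)


def select_signature(
    finding: PathologyFinding,
    gene_ids: Sequence[str],
    p_values: np.ndarray,
    fraction: float,
    statistics: np.ndarray | None = None,
) -> GeneSignature:
    """Keep the ceil(fraction * n_genes) smallest-p genes.

    Ties in p-value are broken toward the larger absolute t statistic
    (when provided) and then lexicographically by gene id, so the
    selection is deterministic and invariant to input column order.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise DataError("cannot select a signature from an empty p-value vector")
    if not 0 < fraction <= 1:
        raise DataError("fraction must be in (0, 1]")
    if len(gene_ids) != p_values.size:
        raise DataError("gene_ids and p_values are misaligned")
    gene_ids = np.asarray([str(g) for g in gene_ids])
    if statistics is None:
        statistics = np.zeros_like(p_values)
    neg_abs_t = -np.abs(np.asarray(statistics, dtype=float))
    # lexsort: last key is primary.
    order = np.lexsort((gene_ids, neg_abs_t, p_values))
    m = signature_size(fraction, p_values.size)
    top = order[:m]
    return GeneSignature(
        finding=finding,
        gene_ids=list(gene_ids[top]),
        p_values=p_values[top],
        fraction=fraction,
    )


def build_signature(
    expr: ExpressionMatrix,
    finding: PathologyFinding,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    fraction: float,
    equal_var: bool = False,
) -> GeneSignature:
    """t-test plus selection in one call, on the given training samples."""
    p, t = t_test_per_gene(
        expr, case_ids, control_ids, equal_var=equal_var, return_statistics=True
    )
    return select_signature(finding, expr.gene_ids, p, fraction, statistics=t)


def write_signature(path: str | Path, sig: GeneSignature) -> None:
    pd.DataFrame({"gene_id": sig.gene_ids, "p_value": sig.p_values}).to_csv(
        path, sep="\t", index=False
    )


def read_signature(
    path: str | Path, finding: PathologyFinding, fraction: float
) -> GeneSignature:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return GeneSignature(
        finding=finding,
        gene_ids=list(df["gene_id"]),
        p_values=df["p_value"].to_numpy(),
        fraction=fraction,
    )
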