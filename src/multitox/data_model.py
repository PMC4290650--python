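"""Core domain types and delimited-text I/O.

The pipeline operates downstream of array normalization, so every table is
plain delimited text: a samples x genes expression matrix of log-scale
intensities, a per-sample annotation (drug, organ), and a binary pathology
occurrence matrix whose columns are histopathology findings labelled
``organ:term`` (e.g. ``liver:Necrosis``).

The canonical in-memory layout is samples in rows. Files are tab-delimited
UTF-8 with one header row and one id column; a comma dialect is available
via the ``sep`` argument but is never inferred. Missing values are an
error, not imputed: the classifiers assume complete normalized matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

ORGANS = ("liver", "kidney")

#: significant decimal digits used when writing expression values; 17 is
#: enough for a float64 round-trip to be bit-exact.
WRITE_PRECISION = 17


class MultitoxError(Exception):
    """Base class for all package errors."""


class DataError(MultitoxError):
    """Malformed or inconsistent input data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class PathologyFinding:
    """A histopathology-graded symptom category in one organ."""

    organ: str
    term: str

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise DataError(
                f"unknown organ tag {self.organ!r}; expected one of {ORGANS}"
            )

    @property
    def label(self) -> str:
        return f"{self.organ}:{self.term}"

    @classmethod
    def from_label(cls, label: str) -> "PathologyFinding":
        organ, sep, term = label.partition(":")
        if not sep or not term:
            raise DataError(
                f"finding label {label!r} is not of the form 'organ:term'"
            )
        return cls(organ=organ, term=term)


@dataclass
class ExpressionMatrix:
    """Normalized expression values, samples in rows and genes in columns."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise DataError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.gene_ids, "gene id")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def sample_rows(self, ids: Iterable[str]) -> np.ndarray:
        try:
            idx = [self._sample_index[s] for s in ids]
        except KeyError as exc:
            raise DataError(f"unknown sample id {exc.args[0]!r}") from None
        return self.values[idx]

    def gene_columns(self, ids: Iterable[str]) -> np.ndarray:
        try:
            idx = [self._gene_index[g] for g in ids]
        except KeyError as exc:
            raise DataError(f"unknown gene id {exc.args[0]!r}") from None
        return self.values[:, idx]

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(list(ids), list(self.gene_ids), self.sample_rows(ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class SampleAnnotation:
    """Per-sample metadata: administered drug and profiled organ."""

    sample_ids: list[str]
    drugs: list[str]
    organs: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.drugs = [str(d) for d in self.drugs]
        self.organs = [str(o) for o in self.organs]
        if not len(self.sample_ids) == len(self.drugs) == len(self.organs):
            raise DataError("annotation columns have inconsistent lengths")
        _check_unique(self.sample_ids, "sample id")
        for sample, organ in zip(self.sample_ids, self.organs):
            if organ not in ORGANS:
                raise DataError(
                    f"sample {sample!r} has unknown organ {organ!r}; "
                    f"expected one of {ORGANS}"
                )
        self._drug_of = dict(zip(self.sample_ids, self.drugs))

    def drug_of(self, sample_id: str) -> str:
        try:
            return self._drug_of[sample_id]
        except KeyError:
            raise DataError(f"unknown sample id {sample_id!r}") from None

    def drugs_of(self, sample_ids: Iterable[str]) -> list[str]:
        return [self.drug_of(s) for s in sample_ids]

    @property
    def unique_drugs(self) -> list[str]:
        return sorted(set(self.drugs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "drug": self.drugs, "organ": self.organs}
        )


@dataclass
class PathologyOccurrenceMatrix:
    """Binary presentation states: entry (i, j) is 1 iff finding j was
    observed in sample i."""

    sample_ids: list[str]
    findings: list[PathologyFinding]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise DataError("occurrence values must be a 2-D matrix")
        if not np.isin(arr, (0, 1)).all():
            i, j = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise DataError(
                f"occurrence entry at sample {self.sample_ids[i]!r}, "
                f"finding {self.findings[j].label!r} is {arr[i, j]!r}, not 0/1"
            )
        self.values = arr.astype(np.int8)
        if self.values.shape != (len(self.sample_ids), len(self.findings)):
            raise DataError(
                f"occurrence shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.findings)} findings"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique([f.label for f in self.findings], "finding")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_findings(self) -> int:
        return len(self.findings)

    def column(self, finding: PathologyFinding) -> np.ndarray:
        return self.values[:, self.findings.index(finding)]

    def subset_samples(self, ids: Sequence[str]) -> "PathologyOccurrenceMatrix":
        try:
            idx = [self._sample_index[s] for s in ids]
        except KeyError as exc:
            raise DataError(f"unknown sample id {exc.args[0]!r}") from None
        return PathologyOccurrenceMatrix(
            list(ids), list(self.findings), self.values[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=self.sample_ids,
            columns=[f.label for f in self.findings],
        )


@dataclass
class StudyConfig:
    """Tunable knobs of the prediction study.

    signature_fraction
        Fraction of genes retained per finding by t-test ranking.
    knn_k
        Neighbors per KNN sub-model; odd by default to avoid 50/50 votes.
    n_submodels
        Jackknife resamples (and hence sub-models) per finding.
    control_subset_size
        Controls drawn per jackknife sample; ``"balanced"`` matches the
        number of cases, the standard undersampling remedy for imbalance.
    cv_folds
        Folds of the drug-grouped cross-validation.
    min_drugs_per_finding
        Keep only findings induced by at least this many distinct drugs;
        0 disables the filter.
    normalization_scheme
        ``"l2"`` divides each similarity row by its Euclidean norm;
        ``"sum_sq"`` divides by the plain sum of squares.
    """

    signature_fraction: float = 0.05
    knn_k: int = 5
    n_submodels: int = 25
    control_subset_size: int | str = "balanced"
    cv_folds: int = 5
    min_drugs_per_finding: int = 0
    normalization_scheme: str = "l2"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.signature_fraction <= 1:
            raise DataError("signature_fraction must be in (0, 1]")
        if self.knn_k < 1:
            raise DataError("knn_k must be a positive integer")
        if self.n_submodels < 1:
            raise DataError("n_submodels must be a positive integer")
        if self.control_subset_size != "balanced":
            if not isinstance(self.control_subset_size, int) or self.control_subset_size < 1:
                raise DataError(
                    "control_subset_size must be a positive integer or 'balanced'"
                )
        if self.cv_folds < 2:
            raise DataError("cv_folds must be at least 2")
        if self.min_drugs_per_finding < 0:
            raise DataError("min_drugs_per_finding must be nonnegative")
        if self.normalization_scheme not in ("l2", "sum_sq"):
            raise DataError("normalization_scheme must be 'l2' or 'sum_sq'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise DataError(f"config file {path} is not a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_seed(self, seed: int) -> "StudyConfig":
        return replace(self, random_seed=seed)


# ---------------------------------------------------------------------------
# Readers / writers


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    return df


def read_expression_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited expression table.

    ``orientation="genes_in_rows"`` transposes the file into the canonical
    samples x genes layout. Duplicate ids, missing cells and non-numeric
    cells are errors that name the offending location.
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise DataError(f"unknown orientation {orientation!r}")
    df = _read_table(path, sep)
    row_what, col_what = (
        ("sample id", "gene id")
        if orientation == "samples_in_rows"
        else ("gene id", "sample id")
    )
    _check_unique(list(df.index), row_what)
    _check_unique(list(df.columns), col_what)
    numeric = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                if cell == "":
                    raise ValueError
                numeric[i, j] = float(cell)
            except ValueError:
                raise DataError(
                    f"missing or non-numeric value {cell!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r} in {path}"
                ) from None
    if orientation == "genes_in_rows":
        return ExpressionMatrix(list(df.columns), list(df.index), numeric.T)
    return ExpressionMatrix(list(df.index), list(df.columns), numeric)


def write_expression_matrix(
    path: str | Path, expr: ExpressionMatrix, sep: str = "\t"
) -> None:
    df = expr.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format=f"%.{WRITE_PRECISION}g")


def read_annotation(path: str | Path, sep: str = "\t") -> SampleAnnotation:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"sample_id", "drug", "organ"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"annotation file {path} lacks columns {sorted(missing)}")
    return SampleAnnotation(
        list(df["sample_id"]), list(df["drug"]), list(df["organ"])
    )


def write_annotation(path: str | Path, ann: SampleAnnotation, sep: str = "\t") -> None:
    ann.to_frame().to_csv(path, sep=sep, index=False)


def read_occurrence_matrix(
    path: str | Path, sep: str = "\t"
) -> PathologyOccurrenceMatrix:
    """Read a binary occurrence table whose header names findings as
    ``organ:term``. Any cell outside {0, 1} is an error with its location."""
    df = _read_table(path, sep)
    findings = [PathologyFinding.from_label(c) for c in df.columns]
    values = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if cell not in ("0", "1"):
                raise DataError(
                    f"occurrence cell {cell!r} at row {df.index[i]!r}, column "
                    f"{df.columns[j]!r} in {path} is not 0 or 1"
                )
            values[i, j] = int(cell)
    return PathologyOccurrenceMatrix(list(df.index), findings, values)


def write_occurrence_matrix(
    path: str | Path, occ: PathologyOccurrenceMatrix, sep: str = "\t"
) -> None:
    df = occ.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Finding filter


def filter_findings(
    occ: PathologyOccurrenceMatrix,
    ann: SampleAnnotation,
    min_drugs: int,
) -> PathologyOccurrenceMatrix:
    """Retain only findings whose case samples span >= ``min_drugs``
    distinct drugs, preserving column order. Idempotent."""
    missing = set(occ.sample_ids) - set(ann.sample_ids)
    if missing:
        raise DataError(
            f"occurrence sample ids absent from annotation: {sorted(missing)[:5]}"
        )
    drugs = np.asarray(ann.drugs_of(occ.sample_ids))
    keep = [
        j
        for j in range(occ.n_findings)
        if len(set(drugs[occ.values[:, j] == 1])) >= min_drugs
    ]
    return PathologyOccurrenceMatrix(
        list(occ.sample_ids),
        [occ.findings[j] for j in keep],
        occ.values[:, keep],
    )
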