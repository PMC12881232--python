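"""Expression-matrix container, normalisation and delimited-text I/O.

The whole package operates on one in-memory container, :class:`ExpressionMatrix`,
a samples x features numeric table with unique string IDs on both axes and an
optional per-sample stage label.  Files are plain delimited text (TSV by
default, CSV accepted) with one header row and one leading ID column; cohort
designs are YAML/JSON mappings from group name to sample-ID list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "CohortDesign",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_feature_list",
    "read_cohort_design",
    "zscore_normalize",
    "subset_features",
]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} ID: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Samples x features numeric matrix with IDs and optional stage labels.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_features)
        Dense numeric expression values; no NaN/inf allowed.
    sample_ids, feature_ids : sequence of str
        Unique identifiers for rows and columns respectively.
    stage_labels : sequence of str, optional
        One label per sample (e.g. the cohort stage it belongs to).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    stage_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain missing/non-finite entries")
        if self.stage_labels is not None:
            self.stage_labels = [str(s) for s in self.stage_labels]
            if len(self.stage_labels) != len(self.sample_ids):
                raise ValueError("stage_labels length must equal number of samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        """Row indices for the given sample IDs (error on unknown ID)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample ID: {e.args[0]!r}") from None

    def take_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index(ids)
        stages = [self.stage_labels[i] for i in idx] if self.stage_labels else None
        return ExpressionMatrix(self.values[idx], list(ids), list(self.feature_ids), stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stage_labels: Sequence[str] | None = None) -> "ExpressionMatrix":
        return cls(
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            list(stage_labels) if stage_labels is not None else None,
        )

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy())


@dataclass
class CohortDesign:
    """Sample-ID sets naming the background (optimal-phenotype), target
    (worst-phenotype) and optional held-out test groups of a cohort."""

    background_ids: list[str]
    target_ids: list[str]
    test_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.background_ids = [str(s) for s in self.background_ids]
        self.target_ids = [str(s) for s in self.target_ids]
        self.test_ids = [str(s) for s in self.test_ids]
        if not self.background_ids or not self.target_ids:
            raise ValueError("background and target groups must both be nonempty")
        overlap = set(self.background_ids) & set(self.target_ids)
        if overlap:
            raise ValueError(f"background and target groups overlap: {sorted(overlap)}")

    def validate_against(self, X: ExpressionMatrix) -> None:
        known = set(X.sample_ids)
        for name, ids in (
            ("background", self.background_ids),
            ("target", self.target_ids),
            ("test", self.test_ids),
        ):
            missing = [i for i in ids if i not in known]
            if missing:
                raise ValueError(f"{name} IDs not present in matrix: {missing}")


def read_expression_tsv(
    path: str | Path,
    orientation: str = "samples-in-rows",
    sep: str | None = None,
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression table into samples x features orientation.

    ``orientation`` says how the *file* is laid out; the returned matrix is
    always samples x features.  Missing / unparseable values are a hard error
    unless ``impute_missing`` is set, in which case they are replaced by the
    per-feature mean.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_cols = sorted({c for c in header if header.count(c) > 1})
    if dup_cols:
        raise ValueError(f"duplicate IDs in {path}: {dup_cols}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.size == 0:
        raise ValueError(f"empty expression matrix in {path}")
    dup_rows = df.index[df.index.duplicated()].unique().tolist()
    if dup_rows:
        raise ValueError(f"duplicate IDs in {path}: {dup_rows}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if orientation == "features-in-rows":
        df = df.T
    if df.isna().any().any():
        if not impute_missing:
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(
                f"missing/unparseable values in {path} (features: {bad[:10]}); "
                "pass impute_missing=True to mean-impute"
            )
        df = df.fillna(df.mean())
    return ExpressionMatrix.from_frame(df)


def write_expression_tsv(X: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    X.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def read_feature_list(path: str | Path) -> list[str]:
    """One feature ID per line; blank lines and '#' comments are skipped."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def read_cohort_design(path: str | Path) -> CohortDesign:
    """YAML or JSON mapping with keys background / target / (optional) test."""
    text = Path(path).read_text()
    if Path(path).suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"cohort design in {path} must be a mapping")
    try:
        background = raw["background"]
        target = raw["target"]
    except KeyError as e:
        raise ValueError(f"cohort design missing group {e.args[0]!r}") from None
    return CohortDesign(list(background), list(target), list(raw.get("test", [])))


def zscore_normalize(X: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Per-feature z-score over all samples (sample sd, denominator n-1).

    Zero-variance features map to all-zeros so downstream correlations see a
    defined (zero) vector.  Requires at least two samples.
    """
    if X.n_samples < 2:
        raise ValueError("z-score normalisation needs at least 2 samples")
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0, ddof=ddof)
    out = np.zeros_like(X.values)
    # "constant" is judged relative to the feature's magnitude so that
    # round-off noise on a flat feature does not get amplified to +-1
    nz = sd > 1e-12 * np.maximum(1.0, np.abs(X.values).max(axis=0))
    out[:, nz] = (X.values[:, nz] - mu[nz]) / sd[nz]
    return replace(X, values=out)


def subset_features(
    X: ExpressionMatrix, keep: Sequence[str]
) -> tuple[ExpressionMatrix, int]:
    """Restrict (and reorder) columns to ``keep``; unknown IDs are skipped.

    Returns the subset matrix and the number of requested IDs not found.
    """
    if not len(keep):
        raise ValueError("feature keep-list is empty")
    lookup = {f: i for i, f in enumerate(X.feature_ids)}
    present = [f for f in keep if f in lookup]
    skipped = len(keep) - len(present)
    if not present:
        raise ValueError("no requested features present in matrix")
    idx = np.array([lookup[f] for f in present], dtype=int)
    sub = ExpressionMatrix(
        X.values[:, idx], list(X.sample_ids), list(present),
        list(X.stage_labels) if X.stage_labels else None,
    )
    return sub, skipped
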