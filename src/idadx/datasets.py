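"""Core dataset container, CSV I/O, and descriptive summaries.

The whole pipeline operates on a :class:`LabeledDataset`: a numeric feature
matrix with named columns plus a binary diagnosis label.  Labels follow the
clinical convention of the source problem — ``True`` means the case was
diagnosed with iron-deficiency anemia, ``False`` means the laboratory values
were not compatible with it.  Which class is "positive" for evaluation is
decided downstream (positive = minority), never at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: accepted spellings for the binary label, lowercased
_TRUE_TOKENS = {"true", "t", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "f", "0", "no", "n"}


class SchemaError(ValueError):
    """The table is structurally unusable (missing label column, no features)."""


class ParseError(ValueError):
    """A feature cell could not be interpreted as a number."""


@dataclass(frozen=True)
class LabeledDataset:
    """Numeric feature matrix with named columns and binary labels.

    Parameters
    ----------
    features : (n, p) float array
    feature_names : names for the p columns
    labels : (n,) boolean array; ``True`` = diseased class of the source data
    name : free-form tag carried through reports
    """

    features: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray
    name: str = ""

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=bool)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, p = X.shape
        if n < 1 or p < 1:
            raise ValueError(f"need at least 1 row and 1 feature, got {n}x{p}")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match feature count")
        if y.shape != (n,):
            raise ValueError("labels length does not match row count")
        if not np.isfinite(X).all():
            raise ValueError("features contain non-finite values")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "feature_names", tuple(str(c) for c in self.feature_names))
        object.__setattr__(self, "labels", y)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[bool, int]:
        return {True: int(self.labels.sum()), False: int((~self.labels).sum())}

    def minority_label(self) -> bool:
        """Smaller class; ties resolve to ``False`` (the healthy class)."""
        c = self.class_counts()
        return c[True] < c[False]

    def subset(self, indices, name: str | None = None) -> "LabeledDataset":
        idx = np.asarray(indices)
        return replace(
            self,
            features=self.features[idx],
            labels=self.labels[idx],
            name=self.name if name is None else name,
        )

    def to_frame(self, label_column: str = "DD") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df[label_column] = np.where(self.labels, "true", "false")
        return df


def _parse_label(token: str, row: int, column: str) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ParseError(f"row {row}, column {column!r}: unrecognized label {token!r}")


def _parse_cell(token: str, row: int, column: str) -> float:
    # accept both "." and "," decimal marks (clinical exports vary by locale)
    t = str(token).strip().replace(",", ".")
    try:
        return float(t)
    except ValueError:
        raise ParseError(
            f"row {row}, column {column!r}: cannot parse {token!r} as a number"
        ) from None


def read_dataset(path, label_column: str = "DD", name: str | None = None) -> LabeledDataset:
    """Read a delimited text table into a :class:`LabeledDataset`.

    The delimiter is sniffed; a header row is required.  Rows containing any
    missing value are dropped with a warning.  Non-numeric feature cells raise
    :class:`ParseError` naming the offending row and column; a missing label
    column raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    if label_column not in df.columns:
        raise SchemaError(
            f"label column {label_column!r} not found; columns are {list(df.columns)}"
        )
    feature_cols = [c for c in df.columns if c != label_column]
    if not feature_cols:
        raise SchemaError("table has no feature columns besides the label")

    missing = df.isna().any(axis=1)
    if missing.any():
        logger.warning(
            "dropping %d row(s) with missing values: %s",
            int(missing.sum()),
            list(df.index[missing][:10]),
        )
        df = df.loc[~missing]
    if len(df) == 0:
        raise SchemaError("no complete rows remain after dropping missing values")

    n = len(df)
    X = np.empty((n, len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        vals = df[col].to_numpy()
        for i, v in enumerate(vals):
            X[i, j] = _parse_cell(v, row=int(df.index[i]), column=col)
    y = np.array(
        [_parse_label(v, int(df.index[i]), label_column) for i, v in enumerate(df[label_column])]
    )
    tag = name if name is not None else str(path)
    return LabeledDataset(X, tuple(feature_cols), y, name=tag)


def write_dataset(ds: LabeledDataset, path, label_column: str = "DD") -> None:
    """Write as CSV with full float precision (round-trips exactly)."""
    ds.to_frame(label_column).to_csv(path, index=False)


@dataclass(frozen=True)
class SummaryTable:
    """Per-feature extrema and class balance (layout of a dataset summary table)."""

    feature_names: tuple[str, ...]
    minima: np.ndarray
    maxima: np.ndarray
    class_counts: dict = field(default_factory=dict)
    imbalance_ratio: float = 1.0  # majority count / minority count; inf if one class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Min": self.minima, "Max": self.maxima}, index=list(self.feature_names)
        )


def summarize(ds: LabeledDataset) -> SummaryTable:
    """Column-wise min/max, class counts, and majority/minority ratio."""
    counts = ds.class_counts()
    lo, hi = min(counts.values()), max(counts.values())
    if lo == 0:
        logger.warning("dataset %r has a single class; imbalance ratio is infinite", ds.name)
        ratio = float("inf")
    else:
        ratio = hi / lo
    return SummaryTable(
        feature_names=ds.feature_names,
        minima=ds.features.min(axis=0),
        maxima=ds.features.max(axis=0),
        class_counts=counts,
        imbalance_ratio=ratio,
    )


def correlation_matrix(ds: LabeledDataset) -> np.ndarray:
    """Symmetric Pearson correlation matrix of the features (unit diagonal).

    Raises ``ValueError`` naming the first zero-variance feature, for which
    the correlation is undefined.
    """
    if ds.n < 3:
        raise ValueError("correlation matrix needs at least 3 rows")
    sd = ds.features.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"feature {ds.feature_names[dead[0]]!r} has zero variance; correlation undefined"
        )
    R = np.corrcoef(ds.features, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)
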