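"""Reading, writing and preprocessing of labeled expression-style tables.

Supports two text dialects: an expression CSV (samples x features, one
designated label column) and the KEEL ``.dat`` benchmark format
(``@relation``/``@attribute``/``@data``). Preprocessing follows the study
protocol: missing values are imputed by the per-class feature mean, features
are min-max normalized to [0, 1], and train/test splits are stratified 80/20.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

logger = logging.getLogger("spiderens")

#: Default mapping from label tokens to the binary {0, 1} encoding.
#: 1 means patient/positive (the class of interest), 0 control/negative.
DEFAULT_LABEL_MAP: Mapping[str, int] = {
    "control": 0,
    "patient": 1,
    "0": 0,
    "1": 1,
}

# Writers emit floats at 6 significant digits so round-trips are bit-exact.
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class LabeledDataset:
    """A samples x features matrix with binary class labels.

    The universal currency of every stage: ``features`` holds real expression
    values (NaN marks missingness until imputation), ``labels`` is a {0, 1}
    vector where 1 is the positive/patient class, and ``feature_names`` /
    ``sample_ids`` are unique identifiers for columns / rows.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, m = self.features.shape
        if not (n == len(self.labels) == len(self.sample_ids)):
            raise ValueError("row count, labels and sample_ids must agree")
        if m != len(self.feature_names):
            raise ValueError("feature count and feature_names must agree")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature_names contains duplicates")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids contains duplicates")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(count of class 0, count of class 1)."""
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def imbalance_ratio(self) -> float:
        """Majority count / minority count; requires both classes present."""
        n0, n1 = self.class_counts()
        if n0 == 0 or n1 == 0:
            raise ValueError("imbalance ratio undefined for single-class data")
        return max(n0, n1) / min(n0, n1)

    def require_both_classes(self) -> None:
        n0, n1 = self.class_counts()
        if n0 == 0 or n1 == 0:
            raise ValueError("dataset must contain both classes")

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        return LabeledDataset(
            self.features[idx],
            self.labels[idx],
            list(self.feature_names),
            [self.sample_ids[i] for i in idx],
        )

    def select_features(self, cols: Sequence[int]) -> "LabeledDataset":
        cols = np.asarray(cols, dtype=int)
        return LabeledDataset(
            self.features[:, cols],
            self.labels,
            [self.feature_names[j] for j in cols],
            list(self.sample_ids),
        )

    def to_frame(self, label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names,
                          index=pd.Index(self.sample_ids, name="sample_id"))
        df[label_column] = self.labels
        return df


@dataclass
class SplitResult:
    """Outcome of a stratified train/test split."""

    train: LabeledDataset
    test: LabeledDataset
    seed: int


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_csv(
    path: str | Path,
    label_column: str,
    label_map: Mapping[str, int] | None = None,
) -> LabeledDataset:
    """Read a samples x features CSV with one label column.

    Empty cells and the token ``NA`` become NaN in the feature matrix; any
    other non-numeric feature cell is a :class:`FormatError` naming the
    offending row and column.
    """
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise FormatError(f"label column {label_column!r} not found in {path}")

    raw_labels = df[label_column].astype(str).str.strip()
    unknown = sorted(set(raw_labels) - set(label_map))
    if unknown:
        raise FormatError(f"unmapped label tokens {unknown} in {path}")
    labels = raw_labels.map(label_map).to_numpy(dtype=int)

    id_col = df.columns[0] if df.columns[0].lower() in ("sample_id", "id", "sample") else None
    feat_cols = [c for c in df.columns if c != label_column and c != id_col]
    sample_ids = (df[id_col].astype(str).tolist() if id_col is not None
                  else [f"s{i}" for i in range(len(df))])

    matrix = np.empty((len(df), len(feat_cols)), dtype=float)
    for j, col in enumerate(feat_cols):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == "" or cell.upper() == "NA":
                matrix[i, j] = np.nan
                continue
            try:
                matrix[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {cell!r} at row {i + 2}, column {col!r} in {path}"
                ) from None
    return LabeledDataset(matrix, labels, feat_cols, sample_ids)


def write_expression_csv(
    data: LabeledDataset, path: str | Path, label_column: str = "class"
) -> None:
    """Write the expression-CSV dialect with 6-significant-digit floats."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("sample_id," + ",".join(data.feature_names) + f",{label_column}\n")
        for i in range(data.n_samples):
            cells = ["" if np.isnan(v) else FLOAT_FORMAT % v for v in data.features[i]]
            fh.write(f"{data.sample_ids[i]}," + ",".join(cells) + f",{data.labels[i]}\n")


_ATTR_RE = re.compile(r"@attribute\s+(\S+)", re.IGNORECASE)


def read_keel(path: str | Path) -> LabeledDataset:
    """Read a KEEL ``.dat`` file; the last attribute is the class.

    The minority class is mapped to label 1 (positive) and the majority to 0,
    so "positive" uniformly means the class of interest. With exactly tied
    class counts, the second-declared (or second-seen) class token is 1.
    """
    path = Path(path)
    attrs: list[str] = []
    data_rows: list[list[str]] = []
    in_data = False
    saw_relation = False
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("@relation"):
                saw_relation = True
            elif low.startswith("@attribute"):
                m = _ATTR_RE.match(line)
                if m is None:
                    raise FormatError(f"malformed @attribute line in {path}: {line!r}")
                attrs.append(m.group(1).rstrip("{").strip())
            elif low.startswith("@data"):
                in_data = True
            elif low.startswith("@"):
                continue  # @inputs/@outputs metadata
            elif in_data:
                data_rows.append([t.strip() for t in line.split(",")])
    if not saw_relation or not attrs:
        raise FormatError(f"{path} lacks a @relation/@attribute header")
    if not in_data:
        raise FormatError(f"{path} lacks an @data section")
    if not data_rows:
        raise FormatError(f"{path} has an empty @data section")

    n_feat = len(attrs) - 1
    class_tokens: list[str] = []
    matrix = np.empty((len(data_rows), n_feat), dtype=float)
    raw_cls: list[str] = []
    for i, row in enumerate(data_rows):
        if len(row) != len(attrs):
            raise FormatError(f"row {i + 1} of {path} has {len(row)} fields, expected {len(attrs)}")
        for j in range(n_feat):
            try:
                matrix[i, j] = float(row[j])
            except ValueError:
                raise FormatError(
                    f"non-numeric value {row[j]!r} at data row {i + 1}, attribute {attrs[j]!r}"
                ) from None
        tok = row[-1]
        raw_cls.append(tok)
        if tok not in class_tokens:
            class_tokens.append(tok)
    if len(class_tokens) != 2:
        raise FormatError(
            f"{path} has {len(class_tokens)} class tokens; only binary problems are supported"
        )
    counts = {t: raw_cls.count(t) for t in class_tokens}
    # minority -> 1; deterministic tie-break: later-declared token is positive
    minority = min(class_tokens[::-1], key=lambda t: counts[t])
    labels = np.array([1 if t == minority else 0 for t in raw_cls], dtype=int)
    return LabeledDataset(
        matrix, labels, attrs[:n_feat], [f"s{i}" for i in range(len(data_rows))]
    )


def write_keel(
    data: LabeledDataset,
    path: str | Path,
    relation: str = "synthetic",
    class_tokens: tuple[str, str] = ("negative", "positive"),
) -> None:
    """Write the KEEL ``.dat`` dialect (class last, 6-significant-digit floats)."""
    neg, pos = class_tokens
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"@relation {relation}\n")
        for name in data.feature_names:
            fh.write(f"@attribute {name} real\n")
        fh.write(f"@attribute class {{{neg}, {pos}}}\n")
        fh.write("@data\n")
        for i in range(data.n_samples):
            cells = [FLOAT_FORMAT % v for v in data.features[i]]
            fh.write(",".join(cells) + "," + (pos if data.labels[i] == 1 else neg) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass
class ImputeStats:
    """Per-class and overall feature means learned from a reference dataset."""

    class_means: dict[int, np.ndarray]
    overall_means: np.ndarray


def fit_imputer(data: LabeledDataset) -> ImputeStats:
    """Learn per-class / overall feature means, ignoring missing cells."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        overall = np.nanmean(data.features, axis=0)
    # features entirely missing overall: mean falls back to 0 (warned on apply)
    overall = np.where(np.isnan(overall), 0.0, overall)
    class_means = {}
    for c in (0, 1):
        rows = data.features[data.labels == c]
        if len(rows) == 0:
            class_means[c] = overall.copy()
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # class-empty columns
            m = np.nanmean(rows, axis=0)
        class_means[c] = np.where(np.isnan(m), overall, m)
    return ImputeStats(class_means=class_means, overall_means=overall)


def impute_class_mean(
    data: LabeledDataset, stats: ImputeStats | None = None
) -> LabeledDataset:
    """Replace missing cells by the feature mean within the sample's class.

    Features entirely missing within a class fall back to the overall feature
    mean; features entirely missing overall are filled with 0 (with a logged
    warning). Idempotent; non-missing cells are never altered.
    """
    if stats is None:
        stats = fit_imputer(data)
        if np.isnan(data.features).all(axis=0).any():
            logger.warning("feature(s) entirely missing; filled with 0")
    out = data.features.copy()
    for c in (0, 1):
        mask = np.isnan(out) & (data.labels == c)[:, None]
        out[mask] = np.broadcast_to(stats.class_means[c], out.shape)[mask]
    return LabeledDataset(out, data.labels, list(data.feature_names), list(data.sample_ids))


@dataclass
class MinMaxParams:
    """Per-feature min/max learned on a reference (training) dataset."""

    mins: np.ndarray
    maxs: np.ndarray


def fit_minmax(data: LabeledDataset) -> MinMaxParams:
    if np.isnan(data.features).any():
        raise ValueError("missing values present; impute before normalization")
    return MinMaxParams(data.features.min(axis=0), data.features.max(axis=0))


def normalize_minmax(
    data: LabeledDataset, params: MinMaxParams | None = None, clip: bool = False
) -> LabeledDataset:
    """Scale each feature to [0, 1] via x' = (x - min) / (max - min).

    Constant features map to all-zeros. With externally supplied ``params``
    (train-fitted) and ``clip=True``, out-of-range values are clipped to
    [0, 1] — the leakage-safe mode used on test splits.
    """
    if np.isnan(data.features).any():
        raise ValueError("missing values present; impute before normalization")
    if params is None:
        params = fit_minmax(data)
    span = params.maxs - params.mins
    safe = np.where(span == 0, 1.0, span)
    out = (data.features - params.mins) / safe
    out[:, span == 0] = 0.0
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return LabeledDataset(out, data.labels, list(data.feature_names), list(data.sample_ids))


def stratified_split(
    data: LabeledDataset, test_fraction: float = 0.2, seed: int = 0
) -> SplitResult:
    """Deterministic stratified split preserving class proportions (+/-1 sample)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n0, n1 = data.class_counts()
    if min(n0, n1) < 2:
        raise ValueError("each class needs at least 2 samples to stratify")
    idx = np.arange(data.n_samples)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=data.labels
    )
    return SplitResult(
        train=data.subset(np.sort(train_idx)),
        test=data.subset(np.sort(test_idx)),
        seed=seed,
    )
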