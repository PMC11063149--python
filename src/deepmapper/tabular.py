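"""Reading, merging, filtering and label-encoding of delimited feature tables.

The pipeline's canonical in-memory form is :class:`FeatureTable`: a dense
``n_obs x F`` matrix of finite floats with named observations (rows) and
features (columns), plus optional integer class labels.  Everything downstream
(normalisation, folding, training) consumes this one container.

Only minimal hygiene is applied here: observations or features that are
entirely zero (or empty, which is read as zero) are dropped.  There is
deliberately no variance filter, imputation or dimension reduction — the whole
point of the approach is to keep the full texture of the data, including what
other pipelines would discard as noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "FilterLog",
    "TableFormatError",
    "load_table",
    "merge_tables",
    "filter_empty",
    "encode_labels",
]


class TableFormatError(ValueError):
    """Raised when an input file or label configuration cannot be used."""


@dataclass
class FilterLog:
    """Record of what :func:`filter_empty` removed."""

    dropped_observations: list[str] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_observations": list(self.dropped_observations),
            "dropped_features": list(self.dropped_features),
        }


@dataclass
class FeatureTable:
    """Observations x features numeric matrix with names and optional labels.

    Attributes
    ----------
    observation_ids:
        Unique opaque row identifiers, length ``n_obs``.
    feature_names:
        Unique column names, length ``F``; order defines the default folding
        order downstream.
    values:
        ``float64`` array of shape ``(n_obs, F)``; every entry finite.
    labels:
        Optional integer class codes in ``[0, n_classes)``, length ``n_obs``.
    label_names:
        Optional mapping ``code -> original label string`` (inverse of the
        encoding applied by :func:`encode_labels`).
    """

    observation_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None
    label_names: dict[int, str] | None = None
    filter_log: FilterLog = field(default_factory=FilterLog)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_obs, n_feat = self.values.shape
        if len(self.observation_ids) != n_obs:
            raise ValueError(
                f"{len(self.observation_ids)} observation ids for {n_obs} rows"
            )
        if len(self.feature_names) != n_feat:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {n_feat} columns"
            )
        if len(set(self.observation_ids)) != n_obs:
            raise ValueError("observation_ids are not unique")
        if len(set(self.feature_names)) != n_feat:
            raise ValueError("feature_names are not unique")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at observation {self.observation_ids[bad[0]]!r}, "
                f"feature {self.feature_names[bad[1]]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (n_obs,):
                raise ValueError("labels length does not match n_obs")
            n_classes = self.n_classes
            if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= max(
                n_classes, 1
            ):
                raise ValueError("label codes outside [0, n_classes)")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            return 0
        if self.label_names:
            return len(self.label_names)
        return int(self.labels.max()) + 1 if self.labels.size else 0


def load_table(
    path,
    delimiter: str = ",",
    label_column: str | None = None,
) -> FeatureTable:
    """Read a delimited table (optionally gzipped) into a :class:`FeatureTable`.

    The first column is used as the observation identifier when it is
    non-numeric and unnamed/index-like is not assumed; otherwise synthetic ids
    ``obs0..`` are assigned.  Column order of the file is preserved as feature
    order.  ``label_column``, when given, is removed from the feature set and
    label-encoded with :func:`encode_labels`.

    Empty cells are read as 0, mirroring the downstream treatment of "0 or
    empty" as removable content.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: file is empty") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise TableFormatError(f"{path}: no data rows")

    if label_column is not None and label_column not in df.columns:
        raise TableFormatError(
            f"{path}: label column {label_column!r} not found "
            f"(columns: {', '.join(map(str, df.columns[:10]))}...)"
        )

    labels = None
    label_names = None
    if label_column is not None:
        raw = df[label_column].astype(str).tolist()
        codes, label_names = encode_labels(raw)
        labels = np.asarray(codes, dtype=np.int64)
        df = df.drop(columns=[label_column])

    first = df.columns[0]
    if df[first].dtype == object and label_column != first:
        obs_ids = df[first].astype(str).tolist()
        df = df.drop(columns=[first])
    else:
        obs_ids = [f"obs{i}" for i in range(len(df))]

    feature_names = [str(c) for c in df.columns]
    values = np.empty((len(df), len(feature_names)), dtype=np.float64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        filled = numeric.fillna(0.0)  # empty cells read as 0
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at row "
                f"{obs_ids[i]!r}, column {col!r}; categorical features must be "
                "converted to numbers before loading"
            )
        values[:, j] = filled.to_numpy(dtype=np.float64)

    return FeatureTable(obs_ids, feature_names, values, labels, label_names)


def merge_tables(tables: list[FeatureTable]) -> FeatureTable:
    """Merge tables feature-wise by exact observation-id join.

    Every table must contain exactly the same set of observation ids; rows are
    aligned to the first table's order.  Unmatched ids are an error — silent
    intersection would hide sample mix-ups.
    """
    if not tables:
        raise ValueError("no tables to merge")
    if len(tables) == 1:
        return tables[0]
    base = tables[0]
    ids = base.observation_ids
    id_set = set(ids)
    names: list[str] = list(base.feature_names)
    blocks = [base.values]
    for t in tables[1:]:
        if set(t.observation_ids) != id_set:
            missing = sorted(id_set.symmetric_difference(t.observation_ids))[:5]
            raise TableFormatError(
                f"observation ids do not match across tables (e.g. {missing})"
            )
        pos = {o: i for i, o in enumerate(t.observation_ids)}
        order = [pos[o] for o in ids]
        blocks.append(t.values[order])
        names.extend(t.feature_names)
    labels = base.labels
    return FeatureTable(ids, names, np.hstack(blocks), labels, base.label_names)


def filter_empty(table: FeatureTable) -> FeatureTable:
    """Drop observations and features whose every entry is 0.

    All surviving values are untouched and keep their original relative order.
    Removed row/column names are recorded on the returned table's
    ``filter_log`` for the run report.  A result with no rows or no columns
    left is an error (the dataset was vacuous).
    """
    zero = table.values == 0.0
    keep_rows = ~zero.all(axis=1)
    keep_cols = ~zero.all(axis=0)
    if not keep_rows.any() or not keep_cols.any():
        raise TableFormatError("all observations or all features are empty")
    log = FilterLog(
        dropped_observations=[
            o for o, k in zip(table.observation_ids, keep_rows) if not k
        ],
        dropped_features=[f for f, k in zip(table.feature_names, keep_cols) if not k],
    )
    out = FeatureTable(
        [o for o, k in zip(table.observation_ids, keep_rows) if k],
        [f for f, k in zip(table.feature_names, keep_cols) if k],
        table.values[np.ix_(keep_rows, keep_cols)],
        table.labels[keep_rows] if table.labels is not None else None,
        dict(table.label_names) if table.label_names is not None else None,
    )
    out.filter_log = log
    return out


def encode_labels(raw_labels: list[str]) -> tuple[list[int], dict[int, str]]:
    """Encode string labels as 0-based codes in lexicographic order.

    Lexicographic assignment makes the coding independent of row order, so
    repeated runs on reshuffled files agree.  A single distinct label is an
    error: there is no classification task.
    """
    distinct = sorted(set(raw_labels))
    if len(distinct) < 2:
        raise TableFormatError(
            f"need at least 2 distinct labels, got {distinct!r}"
        )
    code_of = {name: i for i, name in enumerate(distinct)}
    mapping = {i: name for i, name in enumerate(distinct)}
    return [code_of[r] for r in raw_labels], mapping
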