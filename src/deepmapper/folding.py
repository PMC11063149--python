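"""Normalisation and bijective folding of feature vectors into square images.

A length-``F`` feature vector is placed row-major into the smallest square
``side x side`` matrix with ``side = ceil(sqrt(F))``; the ``side**2 - F``
trailing pixels are zero padding.  Because each pixel holds exactly one
feature, the map is invertible: :func:`pixel_to_feature` recovers the feature
behind any pixel, which is what lets attribution scores be translated back to
named features.  An optional feature ordering (an index) permutes which
feature lands on which pixel; geometry is unchanged.

Values are first log-normalised per feature: shift to non-negative if needed,
``ln(1+x)``, then min-max rescale to [0, 1].  This keeps zero at zero,
compresses the heavy right tails typical of expression counts, and bounds
pixel intensities.  Constant features map to all-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

PADDING = -1
"""Sentinel returned by :func:`pixel_to_feature` for padding pixels."""

__all__ = [
    "PADDING",
    "FoldSpec",
    "log_normalize",
    "compute_fold_spec",
    "fold_vector",
    "unfold_image",
    "pixel_to_feature",
    "fold_dataset",
    "unfold_dataset",
    "read_index_file",
]


@dataclass(frozen=True)
class FoldSpec:
    """Geometry and ordering of the feature -> pixel mapping.

    ``order[p]`` is the feature index occupying flattened pixel position
    ``p`` for ``p < n_features``; positions ``n_features .. side**2 - 1`` are
    zero padding and map to no feature.
    """

    n_features: int
    side: int
    pad_count: int
    order: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "order", np.asarray(self.order, dtype=np.int64)
        )
        if self.side * self.side != self.n_features + self.pad_count:
            raise ValueError("side**2 != n_features + pad_count")
        if self.order.shape != (self.n_features,) or (
            np.sort(self.order) != np.arange(self.n_features)
        ).any():
            raise ValueError("order is not a permutation of [0, n_features)")

    @property
    def inverse_order(self) -> np.ndarray:
        """``inverse_order[f]`` = flattened pixel position holding feature f."""
        inv = np.empty_like(self.order)
        inv[self.order] = np.arange(self.n_features)
        return inv

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "side": self.side,
            "pad_count": self.pad_count,
            "order": self.order.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoldSpec":
        return cls(d["n_features"], d["side"], d["pad_count"], np.asarray(d["order"]))


def log_normalize(values: np.ndarray) -> np.ndarray:
    """Per-feature log normalisation into [0, 1].

    For each column: shift by ``-min`` if the minimum is negative, apply
    ``ln(1+x)``, then min-max rescale.  Monotone per column, so within-feature
    rank order is preserved.  Constant columns become all zeros.
    """
    values = np.asarray(values, dtype=np.float64)
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite value at row {i}, column {j}")
    mins = values.min(axis=0, keepdims=True)
    shifted = np.where(mins < 0, values - mins, values)
    logged = np.log1p(shifted)
    lo = logged.min(axis=0, keepdims=True)
    hi = logged.max(axis=0, keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0  # constant columns -> all zero
    return (logged - lo) / span


def compute_fold_spec(
    n_features: int, order: np.ndarray | None = None
) -> FoldSpec:
    """Smallest-square fold geometry for ``n_features`` features.

    ``side = ceil(sqrt(F))``, e.g. 19,319 features fold into a 139 x 139
    image with 2 padding pixels; 18,225 folds exactly into 135 x 135.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    side = math.isqrt(n_features)
    if side * side < n_features:
        side += 1
    if order is None:
        order = np.arange(n_features, dtype=np.int64)
    return FoldSpec(n_features, side, side * side - n_features, order)


def fold_vector(v: np.ndarray, spec: FoldSpec) -> np.ndarray:
    """Fold one feature vector into its ``side x side`` pseudo-image."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (spec.n_features,):
        raise ValueError(
            f"vector length {v.shape} does not match spec F={spec.n_features}"
        )
    flat = np.zeros(spec.side * spec.side, dtype=np.float64)
    flat[: spec.n_features] = v[spec.order]
    return flat.reshape(spec.side, spec.side)


def unfold_image(image: np.ndarray, spec: FoldSpec) -> np.ndarray:
    """Inverse of :func:`fold_vector`: recover the feature vector."""
    image = np.asarray(image)
    if image.shape != (spec.side, spec.side):
        raise ValueError("image shape does not match spec")
    v = np.empty(spec.n_features, dtype=np.float64)
    v[spec.order] = image.reshape(-1)[: spec.n_features]
    return v


def pixel_to_feature(spec: FoldSpec, row: int, col: int) -> int:
    """Feature index at pixel (row, col), or :data:`PADDING`."""
    if not (0 <= row < spec.side and 0 <= col < spec.side):
        raise ValueError(f"pixel ({row}, {col}) outside {spec.side}x{spec.side}")
    p = row * spec.side + col
    if p >= spec.n_features:
        return PADDING
    return int(spec.order[p])


def fold_dataset(table, spec: FoldSpec) -> tuple[np.ndarray, np.ndarray | None]:
    """Fold every observation of a (normalised) table into a 1-channel image set.

    Returns ``(images, labels)`` with images of shape
    ``(n_obs, 1, side, side)``; labels pass through unchanged.
    """
    if table.n_features != spec.n_features:
        raise ValueError(
            f"table has {table.n_features} features, spec expects {spec.n_features}"
        )
    n = table.n_obs
    flat = np.zeros((n, spec.side * spec.side), dtype=np.float64)
    flat[:, : spec.n_features] = table.values[:, spec.order]
    images = flat.reshape(n, 1, spec.side, spec.side)
    return images, (None if table.labels is None else table.labels.copy())


def unfold_dataset(images: np.ndarray, spec: FoldSpec) -> np.ndarray:
    """Recover the ``n_obs x F`` matrix from a folded image set."""
    images = np.asarray(images)
    n = images.shape[0]
    flat = images.reshape(n, -1)
    out = np.empty((n, spec.n_features), dtype=np.float64)
    out[:, spec.order] = flat[:, : spec.n_features]
    return out


def read_index_file(path, feature_names: list[str]) -> np.ndarray:
    """Read a two-column (feature_name, rank) CSV into a folding order.

    The returned ``order`` places the rank-0 feature on pixel 0, rank-1 on
    pixel 1, and so on.  Every feature of the table must be ranked exactly
    once.
    """
    df = pd.read_csv(path, header=0)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: index file must have exactly 2 columns")
    name_to_idx = {n: i for i, n in enumerate(feature_names)}
    ranked = df.sort_values(df.columns[1], kind="stable")
    names = [str(x) for x in ranked.iloc[:, 0]]
    if sorted(names) != sorted(feature_names):
        raise ValueError(f"{path}: index features do not match table features")
    return np.asarray([name_to_idx[n] for n in names], dtype=np.int64)
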