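"""Synthetic benchmarks: needle-in-a-haystack tables, pixel shuffles, toy images.

The needle-in-a-haystack (NIHS) dataset hides a tiny planted signal inside a
large block of uniform noise: all features are i.i.d. Uniform[0, 1) except a
handful of *informative* features whose values are drawn from narrow
class-conditional sub-ranges.  By default two features are planted in a
10,000 x 18,225 table:

========== ============== ==============
feature     class-0 range  class-1 range
========== ============== ==============
20          [0.00, 0.20)   [0.20, 0.40)
17,998      [0.10, 0.20)   [0.25, 0.35)
========== ============== ==============

Both planted features have disjoint class-conditional supports, so a single
threshold on either separates the classes perfectly — which gives every
downstream recovery test an exact oracle.  All draws are reproducible from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tabular import FeatureTable

__all__ = [
    "InformativeFeatureSpec",
    "NIHSConfig",
    "default_informative_features",
    "generate_nihs",
    "shuffle_pixels",
    "unshuffle_pixels",
    "generate_toy_patterns",
]


@dataclass(frozen=True)
class InformativeFeatureSpec:
    """One planted feature: a column index and per-class value ranges.

    ``class_ranges`` maps each class code to a half-open interval
    ``[low, high)`` within [0, 1).  Half-open intervals keep adjacent class
    supports (e.g. 0.00-0.20 and 0.20-0.40) disjoint at the shared endpoint.
    """

    feature_index: int
    class_ranges: dict[int, tuple[float, float]]

    def __post_init__(self) -> None:
        for c, (lo, hi) in self.class_ranges.items():
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(
                    f"feature {self.feature_index}, class {c}: "
                    f"invalid range [{lo}, {hi})"
                )


def default_informative_features() -> list[InformativeFeatureSpec]:
    """The two standard planted features (indices 20 and 17,998)."""
    return [
        InformativeFeatureSpec(20, {0: (0.00, 0.20), 1: (0.20, 0.40)}),
        InformativeFeatureSpec(17_998, {0: (0.10, 0.20), 1: (0.25, 0.35)}),
    ]


@dataclass
class NIHSConfig:
    n_obs: int = 10_000
    n_features: int = 18_225
    informative: list[InformativeFeatureSpec] = field(
        default_factory=default_informative_features
    )
    n_classes: int = 2
    class_balance: tuple[float, ...] | None = None  # None -> equal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_balance is None:
            self.class_balance = tuple([1.0 / self.n_classes] * self.n_classes)
        if abs(sum(self.class_balance) - 1.0) > 1e-9:
            raise ValueError("class_balance must sum to 1")
        idx = [s.feature_index for s in self.informative]
        if len(set(idx)) != len(idx):
            raise ValueError("informative feature indices must be distinct")
        for s in self.informative:
            if s.feature_index >= self.n_features:
                raise ValueError(
                    f"informative index {s.feature_index} >= n_features "
                    f"{self.n_features}"
                )


def _assign_labels(config: NIHSConfig, rng: np.random.Generator) -> np.ndarray:
    """Class labels matching class_balance as exactly as possible, shuffled."""
    counts = np.floor(np.asarray(config.class_balance) * config.n_obs).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    frac = np.asarray(config.class_balance) * config.n_obs - counts
    for c in np.argsort(-frac)[: config.n_obs - counts.sum()]:
        counts[c] += 1
    labels = np.repeat(np.arange(config.n_classes), counts)
    return rng.permutation(labels)


def generate_nihs(config: NIHSConfig) -> FeatureTable:
    """Generate a needle-in-a-haystack feature table.

    Non-informative cells are Uniform[0, 1); the cell of an informative
    feature for an observation of class ``c`` is Uniform over that feature's
    class-``c`` range.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    labels = _assign_labels(config, rng)
    values = rng.random((config.n_obs, config.n_features))
    for spec in config.informative:
        col = rng.random(config.n_obs)  # fresh draws, then squeezed per class
        for c, (lo, hi) in spec.class_ranges.items():
            mask = labels == c
            values[mask, spec.feature_index] = lo + (hi - lo) * col[mask]
    obs_ids = [f"obs{i}" for i in range(config.n_obs)]
    feature_names = [f"var{j}" for j in range(config.n_features)]
    label_names = {c: f"class{c}" for c in range(config.n_classes)}
    return FeatureTable(obs_ids, feature_names, values, labels, label_names)


def shuffle_pixels(
    images: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one seeded flat-position permutation identically to every image.

    Returns ``(shuffled, permutation)`` where
    ``shuffled_flat[:, p] = flat[:, permutation[p]]``.  The permutation is
    returned so the operation can be inverted with :func:`unshuffle_pixels`.
    """
    images = np.asarray(images)
    if images.shape[0] == 0:
        raise ValueError("empty image set")
    n = images.shape[0]
    flat = images.reshape(n, -1)
    perm = np.random.default_rng(seed).permutation(flat.shape[1])
    return flat[:, perm].reshape(images.shape), perm


def unshuffle_pixels(images: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Invert :func:`shuffle_pixels` given the returned permutation."""
    images = np.asarray(images)
    n = images.shape[0]
    flat = images.reshape(n, -1)
    out = np.empty_like(flat)
    out[:, perm] = flat
    return out.reshape(images.shape)


def generate_toy_patterns(
    n_obs: int,
    side: int = 28,
    n_classes: int = 2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled template-plus-noise images for fast trainer/shuffle tests.

    Each class has a fixed template: a bright rectangle at a class-specific
    position on a dark background.  Images are the template plus i.i.d.
    Gaussian noise, clipped to [0, 1].  Labels are balanced to within one
    observation.  Returns ``(images, labels)`` with images of shape
    ``(n_obs, 1, side, side)``.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_obs < n_classes:
        raise ValueError("need at least one observation per class")
    rng = np.random.default_rng(seed)

    h = max(2, side // 4)
    templates = np.zeros((n_classes, side, side))
    for c in range(n_classes):
        # rectangles tile distinct positions; distinct for any n_classes <= 16
        r0 = min((c % 4) * h, side - h)
        c0 = min((c // 4) * h, side - h)
        templates[c, r0 : r0 + h, c0 : c0 + h] = 0.8

    base = np.arange(n_obs) % n_classes
    labels = rng.permutation(base)
    images = templates[labels][:, None, :, :]
    if noise_sd > 0:
        images = images + rng.normal(0.0, noise_sd, size=images.shape)
    images = np.clip(images, 0.0, 1.0)
    return images, labels.astype(np.int64)
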