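"""Seeded train/test cycles of the CNN classifier, iterated to convergence.

One *iteration* is a fresh stratified split, a freshly initialised network,
training for up to ``epochs`` epochs (stopping early once the held-out
accuracy target is reached), and attribution of the correctly classified
held-out samples.  Iterations repeat — each with a different derived seed —
until the best held-out accuracy stabilises or ``max_iterations`` is hit;
attributions are pooled over all iterations so that a lucky or unlucky single
initialisation cannot dominate the feature ranking.

Every stochastic stage draws its seed deterministically from
``(config.seed, iteration, stage name)``, so a run is reproducible from the
one user-facing seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import train_test_split

from . import folding
from .attribution import (
    AttributionAccumulator,
    AttributionSummary,
    FeatureRanking,
    attribute_correct,
    rank_features,
)
from .nn import Adam, ResidualCNN, make_network, softmax_cross_entropy
from .tabular import FeatureTable, filter_empty

__all__ = [
    "RunConfig",
    "IterationResult",
    "PipelineResult",
    "derive_seed",
    "split_data",
    "build_model",
    "train_model",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Hyperparameters of a full pipeline run.

    ``holdout_fraction`` defaults to 0.375 so that a 10,000-observation run
    holds out 3,750 samples.  ``accuracy_target`` is both the early-stopping
    threshold within an iteration (training past a good fit mostly buys
    overfitting) and part of the convergence rule across iterations.
    """

    holdout_fraction: float = 0.375
    epochs: int = 15
    max_iterations: int = 5
    accuracy_target: float = 0.95
    convergence_tol: float = 0.005
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    arch: str = "resnet18"
    attribution_method: str = "integrated-gradients"

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.epochs < 1 or self.max_iterations < 1:
            raise ValueError("epochs and max_iterations must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IterationResult:
    """Metrics and held-out outcomes of one train/test cycle."""

    train_loss: list[float]
    train_accuracy: list[float]
    test_loss: list[float]
    test_accuracy: list[float]
    predictions: np.ndarray          # final predicted class per held-out sample
    correct: np.ndarray              # bool, aligned with predictions
    train_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    test_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    model: ResidualCNN | None = None

    @property
    def epochs_run(self) -> int:
        return len(self.test_accuracy)

    @property
    def best_test_accuracy(self) -> float:
        return max(self.test_accuracy)


@dataclass
class PipelineResult:
    iterations: list[IterationResult]
    summary: AttributionSummary
    ranking: FeatureRanking
    fold_spec: folding.FoldSpec
    config: RunConfig
    feature_names: list[str]
    label_names: dict[int, str] | None
    filter_log: dict

    @property
    def final_test_accuracies(self) -> list[float]:
        return [it.best_test_accuracy for it in self.iterations]


def derive_seed(seed: int, iteration: int, stage: str) -> int:
    """Deterministic, well-separated seed for one stochastic stage."""
    digest = hashlib.sha256(f"{seed}/{iteration}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def split_data(
    n_obs: int, labels: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified, seeded train/held-out split.

    The held-out set has exactly ``round(n_obs * fraction)`` members, with
    per-class counts proportional to the class sizes (within one observation).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be strictly between 0 and 1")
    labels = np.asarray(labels)
    if labels.shape != (n_obs,):
        raise ValueError("labels length must equal n_obs")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 observations to split")
    n_test = int(round(n_obs * fraction))
    train_idx, test_idx = train_test_split(
        np.arange(n_obs),
        test_size=n_test,
        stratify=labels,
        random_state=seed % (2**32 - 1),
    )
    return np.sort(train_idx), np.sort(test_idx)


def build_model(
    side: int, n_classes: int, arch: str = "resnet18", seed: int = 0
) -> ResidualCNN:
    """Build a residual CNN for 1-channel ``side x side`` inputs.

    Global average pooling makes the same weights valid for any side >= 16,
    so 135 x 135 and 139 x 139 images run through one code path.
    """
    if side < 16:
        raise ValueError("side must be >= 16")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return make_network(arch, n_classes, seed=seed)


def _evaluate(
    model: ResidualCNN, images: np.ndarray, labels: np.ndarray,
    batch_size: int = 256,
) -> tuple[float, float, np.ndarray]:
    losses, preds = [], []
    for i in range(0, images.shape[0], batch_size):
        logits = model.forward(images[i : i + batch_size], train=False)
        loss, _ = softmax_cross_entropy(logits, labels[i : i + batch_size])
        losses.append(loss * logits.shape[0])
        preds.append(logits.argmax(axis=1))
    preds = np.concatenate(preds)
    return (
        float(np.sum(losses) / images.shape[0]),
        float((preds == labels).mean()),
        preds,
    )


def train_model(
    model: ResidualCNN,
    train_set: tuple[np.ndarray, np.ndarray],
    test_set: tuple[np.ndarray, np.ndarray],
    config: RunConfig,
    seed: int | None = None,
) -> IterationResult:
    """Train for up to ``config.epochs`` epochs with held-out monitoring.

    Stops early once held-out accuracy reaches ``config.accuracy_target``.
    Records per-epoch train/test loss and accuracy and, at the end, the
    per-sample predictions and correctness flags on the held-out set.
    """
    x_train, y_train = train_set
    x_test, y_test = test_set
    if x_train.shape[0] == 0 or x_test.shape[0] == 0:
        raise ValueError("train and test sets must be non-empty")
    x_train = np.asarray(x_train, dtype=np.float32)
    x_test = np.asarray(x_test, dtype=np.float32)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    opt = Adam(model.params(), lr=config.learning_rate)

    tr_loss, tr_acc, te_loss, te_acc = [], [], [], []
    preds = None
    for epoch in range(config.epochs):
        order = rng.permutation(x_train.shape[0])
        losses, hits, seen = 0.0, 0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(x_train[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training loss became non-finite at epoch {epoch} "
                    f"(learning rate {config.learning_rate})"
                )
            model.backward(dlogits)
            opt.step()
            losses += loss * len(idx)
            hits += int((logits.argmax(axis=1) == y_train[idx]).sum())
            seen += len(idx)
        tr_loss.append(losses / seen)
        tr_acc.append(hits / seen)
        loss_t, acc_t, preds = _evaluate(model, x_test, y_test)
        te_loss.append(loss_t)
        te_acc.append(acc_t)
        if acc_t >= config.accuracy_target:
            break

    return IterationResult(
        train_loss=tr_loss,
        train_accuracy=tr_acc,
        test_loss=te_loss,
        test_accuracy=te_acc,
        predictions=preds,
        correct=preds == y_test,
        model=model,
    )


def run_pipeline(
    table: FeatureTable,
    config: RunConfig,
    order: np.ndarray | None = None,
) -> PipelineResult:
    """Full supervised run: normalise, fold, iterate train/attribute, rank.

    Stops before ``max_iterations`` when the best held-out accuracy changed by
    less than ``convergence_tol`` between two successive iterations and the
    accuracy target has been met (a tolerance >= 1 disables the target check
    and simply stops after two iterations).  The final feature ranking pools
    the attribution maps of every correctly classified held-out sample across
    all iterations, with equal weight per sample.
    """
    if table.labels is None:
        raise ValueError("run_pipeline requires a labelled table")
    n_classes = table.n_classes
    if n_classes < 2:
        raise ValueError("need at least 2 classes")

    table = filter_empty(table)
    normalized = folding.log_normalize(table.values)
    norm_table = FeatureTable(
        table.observation_ids,
        table.feature_names,
        normalized,
        table.labels,
        table.label_names,
    )
    spec = folding.compute_fold_spec(table.n_features, order)
    images, labels = folding.fold_dataset(norm_table, spec)
    images = images.astype(np.float32)

    iterations: list[IterationResult] = []
    accumulator = AttributionAccumulator(
        n_classes, spec.side, method=config.attribution_method
    )
    for it in range(config.max_iterations):
        try:
            train_idx, test_idx = split_data(
                table.n_obs, labels, config.holdout_fraction,
                derive_seed(config.seed, it, "split"),
            )
            model = build_model(
                spec.side, n_classes, config.arch,
                seed=derive_seed(config.seed, it, "init"),
            )
            result = train_model(
                model,
                (images[train_idx], labels[train_idx]),
                (images[test_idx], labels[test_idx]),
                config,
                seed=derive_seed(config.seed, it, "train"),
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline iteration {it} failed: {exc}") from exc
        result.train_indices = train_idx
        result.test_indices = test_idx
        iterations.append(result)

        maps, mask = attribute_correct(
            model,
            images[test_idx],
            labels[test_idx],
            result.predictions,
            method=config.attribution_method,
        )
        accumulator.add(maps, labels[test_idx][mask])

        if it >= 1:
            prev, best = (
                iterations[-2].best_test_accuracy,
                iterations[-1].best_test_accuracy,
            )
            converged = abs(best - prev) < config.convergence_tol and (
                best >= config.accuracy_target or config.convergence_tol >= 1.0
            )
            if converged:
                break

    summary = accumulator.finalize()
    ranking = rank_features(summary, spec, table.feature_names)
    return PipelineResult(
        iterations=iterations,
        summary=summary,
        ranking=ranking,
        fold_spec=spec,
        config=config,
        feature_names=table.feature_names,
        label_names=table.label_names,
        filter_log=table.filter_log.to_dict(),
    )
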