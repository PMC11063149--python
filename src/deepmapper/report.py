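"""Run reports: JSON summary, ranking CSVs, metric curves, heatmaps, manifest.

A completed pipeline run is summarised into a :class:`RunReport` — a plain
serialisable structure a user (or a later process) can archive — and written
to a directory by :func:`write_report`.  Everything written is listed in a
manifest with SHA-256 checksums so archived runs can be verified.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attribution import OVERALL
from .training import PipelineResult

__all__ = ["RunReport", "build_report", "write_report", "write_history"]


@dataclass
class RunReport:
    """Serialisable summary of one pipeline run."""

    config: dict
    filter_log: dict
    fold_spec: dict
    n_iterations: int
    metrics: list[dict]           # one record per iteration: per-epoch curves
    accuracy_mean: float          # mean of best held-out accuracy per iteration
    accuracy_sd: float
    n_attributed_per_class: list[int]
    label_names: dict | None = None
    artifacts: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "filter_log": self.filter_log,
            "fold_spec": self.fold_spec,
            "n_iterations": self.n_iterations,
            "metrics": self.metrics,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "n_attributed_per_class": self.n_attributed_per_class,
            "label_names": self.label_names,
            "artifacts": self.artifacts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(**d)


def build_report(result: PipelineResult) -> RunReport:
    accs = np.asarray(result.final_test_accuracies, dtype=float)
    spec_dict = result.fold_spec.to_dict()
    identity = np.array_equal(
        result.fold_spec.order, np.arange(result.fold_spec.n_features)
    )
    if identity:
        spec_dict["order"] = "identity"
    metrics = [
        {
            "iteration": i,
            "train_loss": [float(v) for v in it.train_loss],
            "train_accuracy": [float(v) for v in it.train_accuracy],
            "test_loss": [float(v) for v in it.test_loss],
            "test_accuracy": [float(v) for v in it.test_accuracy],
            "epochs_run": it.epochs_run,
            "n_test": int(len(it.test_indices)),
        }
        for i, it in enumerate(result.iterations)
    ]
    return RunReport(
        config=result.config.to_dict(),
        filter_log=result.filter_log,
        fold_spec=spec_dict,
        n_iterations=len(result.iterations),
        metrics=metrics,
        accuracy_mean=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        n_attributed_per_class=[
            int(n) for n in result.summary.n_samples_per_class
        ],
        label_names=(
            {str(k): v for k, v in result.label_names.items()}
            if result.label_names
            else None
        ),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _plot_curves(result: PipelineResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_l, ax_a) = plt.subplots(1, 2, figsize=(9, 3.5))
    for i, it in enumerate(result.iterations):
        epochs = np.arange(1, it.epochs_run + 1)
        ax_l.plot(epochs, it.train_loss, "--", label=f"train it{i}")
        ax_l.plot(epochs, it.test_loss, "-", label=f"test it{i}")
        ax_a.plot(epochs, it.train_accuracy, "--")
        ax_a.plot(epochs, it.test_accuracy, "-")
    ax_l.set_xlabel("epoch"); ax_l.set_ylabel("loss"); ax_l.legend(fontsize=6)
    ax_a.set_xlabel("epoch"); ax_a.set_ylabel("accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_heatmap(mean_map: np.ndarray, title: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(mean_map, cmap="magma")
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_history(result: PipelineResult, path: Path) -> None:
    """Per-epoch JSON-lines history (one record per epoch per iteration)."""
    with open(path, "w") as fh:
        for i, it in enumerate(result.iterations):
            for e in range(it.epochs_run):
                fh.write(
                    json.dumps(
                        {
                            "iteration": i,
                            "epoch": e,
                            "train_loss": float(it.train_loss[e]),
                            "train_accuracy": float(it.train_accuracy[e]),
                            "test_loss": float(it.test_loss[e]),
                            "test_accuracy": float(it.test_accuracy[e]),
                        }
                    )
                    + "\n"
                )


def write_report(result: PipelineResult, out_dir) -> dict:
    """Write the full run archive; returns the manifest (file -> sha256).

    Writes ``report.json``, one ranking CSV per class plus the overall
    ranking, per-class attribution heatmaps and per-pixel mean matrices,
    metric curves, the per-epoch history, and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for c in sorted(result.ranking.table["class"].unique()):
        tag = "overall" if c == OVERALL else f"class{c}"
        p = out / f"ranking_{tag}.csv"
        sub = result.ranking.table[result.ranking.table["class"] == c]
        sub.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    for c in range(result.summary.n_classes):
        p = out / f"attribution_class{c}.csv"
        np.savetxt(p, result.summary.per_class_mean[c], fmt="%.8g", delimiter=",")
        written.append(p)
        p = out / f"heatmap_class{c}.png"
        _plot_heatmap(
            result.summary.per_class_mean[c], f"mean |attribution|, class {c}", p
        )
        written.append(p)

    p = out / "curves.png"
    _plot_curves(result, p)
    written.append(p)

    p = out / "history.jsonl"
    write_history(result, p)
    written.append(p)

    report = build_report(result)
    report.artifacts = [str(w.name) for w in written]
    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    written.append(p)

    manifest = {w.name: _sha256(w) for w in written}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
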