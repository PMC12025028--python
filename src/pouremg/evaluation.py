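"""Evaluation: confusion matrices, accuracy / sensitivity / specificity,
coarsened scoring, and classical feature-only baselines.

Metrics follow the usual one-vs-rest decomposition: for class c, with
TP, TN, FP, FN counted against all other classes,

* accuracy    = (TP + TN) / (TP + TN + FP + FN)  — overall, this equals
  trace(confusion) / total;
* sensitivity = TP / (TP + FN)  (recall);
* specificity = TN / (TN + FP).

For multiclass tasks the headline sensitivity/specificity are unweighted
(macro) means over classes; classes with a zero denominator (no true
positives possible, or no negatives) are excluded from the mean rather
than counted as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .granular_labels import Level, N_CLASSES, coarsen, coarsen_probabilities, membership_matrix

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "metrics",
    "coarsen_confusion",
    "evaluate",
    "run_baselines",
    "plot_confusion",
]


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of windows with true class i predicted as j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class c."""
        tp = int(self.counts[c, c])
        fn = int(self.counts[c].sum()) - tp
        fp = int(self.counts[:, c].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float  # macro
    specificity: float  # macro
    per_class_sensitivity: list[float]
    per_class_specificity: list[float]
    level: str | None = None
    confusion: ConfusionMatrix | None = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_class_sensitivity": self.per_class_sensitivity,
            "per_class_specificity": self.per_class_specificity,
            "confusion": None if self.confusion is None else self.confusion.counts.tolist(),
        }


def confusion(y_true, y_pred, k: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= k or y_pred.min() < 0 or y_pred.max() >= k
    ):
        raise ValueError(f"class indices out of range 0..{k - 1}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def metrics(cm: ConfusionMatrix, level: str | None = None) -> EvalReport:
    """Accuracy plus macro-averaged one-vs-rest sensitivity/specificity."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(cm.counts) / cm.total)
    sens, spec = [], []
    for c in range(cm.k):
        tp, tn, fp, fn = cm.one_vs_rest(c)
        sens.append(tp / (tp + fn) if tp + fn > 0 else float("nan"))
        spec.append(tn / (tn + fp) if tn + fp > 0 else float("nan"))
    macro_sens = float(np.nanmean(sens)) if not all(np.isnan(sens)) else float("nan")
    macro_spec = float(np.nanmean(spec)) if not all(np.isnan(spec)) else float("nan")
    return EvalReport(acc, macro_sens, macro_spec, sens, spec, level=level, confusion=cm)


def coarsen_confusion(
    cm: ConfusionMatrix, from_level: Level | str, to_level: Level | str
) -> ConfusionMatrix:
    """Aggregate a fine confusion matrix over granules: G @ cm @ G.T for
    the 0/1 membership matrix G."""
    g = membership_matrix(from_level, to_level)
    return ConfusionMatrix(g @ cm.counts @ g.T)


def evaluate(
    model,
    windows,
    labels_fine,
    level: Level | str,
    features: np.ndarray | None = None,
    report_coarsened: bool = False,
    mode: str = "probability",
):
    """Score a trained model at its native granularity and optionally after
    coarsening to the 4 primary categories.

    ``mode='probability'`` coarsens by summing predicted class
    probabilities over granules before the argmax (uses the full model
    output); ``mode='argmax'`` maps the fine argmax through the
    coarsening function.
    """
    from .convmixer import predict

    level = Level(level)
    k = N_CLASSES[level]
    if getattr(model, "config", None) is not None and model.config.n_classes != k:
        raise ValueError(f"model has {model.config.n_classes} classes, {level.value} needs {k}")
    y_fine = np.asarray(labels_fine, dtype=int)
    pred, probs = predict(model, windows, features)
    fine_report = metrics(confusion(y_fine, pred, k), level=level.value)
    if not report_coarsened or level is Level.COARSE:
        return (fine_report, fine_report) if report_coarsened else fine_report
    y_coarse = np.array([coarsen(y, level, Level.COARSE) for y in y_fine])
    if mode == "probability":
        coarse_probs = coarsen_probabilities(probs, level, Level.COARSE)
        pred_coarse = coarse_probs.argmax(axis=1)
    elif mode == "argmax":
        pred_coarse = np.array([coarsen(p, level, Level.COARSE) for p in pred])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    coarse_report = metrics(
        confusion(y_coarse, pred_coarse, N_CLASSES[Level.COARSE]), level=Level.COARSE.value
    )
    return fine_report, coarse_report


def run_baselines(
    features: np.ndarray,
    labels,
    level: Level | str,
    seed: int = 0,
    train_idx=None,
    test_idx=None,
    test_size: float = 0.25,
) -> dict[str, EvalReport]:
    """Classical classifiers on the 16-dim handcrafted features alone:
    support-vector machine, random forest and linear discriminant
    analysis (library defaults, fixed seed).  Features are standardised
    with statistics from the training split."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split
    from sklearn.svm import SVC

    from .features import fit_scaler

    level = Level(level)
    k = N_CLASSES[level]
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if train_idx is None:
        train_idx, test_idx = train_test_split(
            np.arange(len(y)), test_size=test_size, random_state=seed, stratify=y
        )
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("degenerate split: fewer than 2 classes in training data")
    scaler = fit_scaler(x[train_idx])
    xtr, xte = scaler.transform(x[train_idx]), scaler.transform(x[test_idx])
    ytr, yte = y[train_idx], y[test_idx]
    models = {
        "svm": SVC(random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
        "lda": LinearDiscriminantAnalysis(),
    }
    out: dict[str, EvalReport] = {}
    for name, clf in models.items():
        clf.fit(xtr, ytr)
        pred = clf.predict(xte)
        out[name] = metrics(confusion(yte, pred, k), level=level.value)
    return out


def export_report(report: EvalReport, out_dir, stem: str = "report") -> None:
    """JSON metrics + CSV confusion matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{stem}.json").write_text(json.dumps(report.to_dict(), indent=2))
    if report.confusion is not None:
        pd.DataFrame(report.confusion.counts).to_csv(out_dir / f"{stem}_confusion.csv")


def plot_confusion(cm: ConfusionMatrix, path, class_names: list[str] | None = None) -> None:
    """Heatmap of the confusion matrix (true classes on Y, predicted on X,
    direction blocks in the fine ordering)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xlabel("predicted label")
    ax.set_ylabel("true label")
    if class_names is not None:
        ax.set_xticks(range(cm.k), class_names, rotation=90, fontsize=7)
        ax.set_yticks(range(cm.k), class_names, fontsize=7)
    for i in range(cm.k):
        for j in range(cm.k):
            if cm.counts[i, j]:
                ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center", fontsize=6)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
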