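"""Training, cross-validation and scoring of the pocket classifier.

The dataset-level score is

    Sacc = sum_c N_c^TP / sum_c N_c      over classes c in L,

where a prediction is a true positive only when the full 0/1 label vector
matches the observed one exactly.  Confusion matrices are tabulated per
cross-validation fold over the class list plus the catch-all ``Others``
outcome (the all-zero or otherwise non-class label vector), normalized per
observed row, and reported as mean +/- sd over folds alongside the combined
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .function import OTHERS, decode_labels, scheme_classes


@dataclass
class TrainConfig:
    """Optimization protocol: plain SGD on binary cross-entropy."""

    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def train(model: nn.Network, X: np.ndarray, Y: np.ndarray, config: TrainConfig) -> list[float]:
    """Train in place; returns the mean training loss per epoch.

    Deterministic for a fixed ``config.seed`` (which drives both the epoch
    shuffles and the dropout masks).
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    X = np.asarray(X, dtype=nn.F4)
    Y = np.asarray(Y, dtype=nn.F4)
    rng = np.random.default_rng(config.seed)
    model.set_dropout_rng(np.random.default_rng(rng.integers(2**31)))
    losses: list[float] = []
    m = len(X)
    for _ in range(config.epochs):
        order = rng.permutation(m)
        epoch_loss = 0.0
        for start in range(0, m, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward_logits(X[idx], train=True)
            loss, grad = nn.bce_loss_and_grad(logits, Y[idx])
            model.backward_from_logits(grad)
            model.sgd_step(config.learning_rate)
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / m)
        if not np.isfinite(losses[-1]):
            raise FloatingPointError("training loss diverged")
    return losses


def predict_labels(model: nn.Network, grids: np.ndarray) -> np.ndarray:
    """Threshold each sigmoid output at 0.5 into a 0/1 label vector."""
    X = np.asarray(grids, dtype=nn.F4)
    single = X.ndim == 4
    if single:
        X = X[None]
    probs = model.forward(X, train=False)
    labels = (probs >= 0.5).astype(int)
    return labels[0] if single else labels


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def stratified_folds(class_names: list[str], k: int, seed: int) -> np.ndarray:
    """Fold index per sample; per-class fold sizes differ by at most one."""
    rng = np.random.default_rng(seed)
    assignment = np.full(len(class_names), -1, dtype=int)
    classes = sorted(set(class_names))
    offset = 0
    for cls in classes:
        idx = np.array([i for i, c in enumerate(class_names) if c == cls])
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has {len(idx)} samples, fewer than k={k}")
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            assignment[i] = (pos + offset) % k
        offset += len(idx)
    return assignment


# ---------------------------------------------------------------------------
# confusion bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class ConfusionSummary:
    """Per-fold and combined confusion counts for a fixed class list.

    Rows are observed classes (the list ``classes``); columns are predicted
    outcomes: the same classes followed by ``Others``.
    """

    classes: list[str]
    fold_counts: np.ndarray  # (k, |L|, |L|+1) integers

    def __post_init__(self) -> None:
        self.fold_counts = np.asarray(self.fold_counts, dtype=int)
        k, nr, nc = self.fold_counts.shape
        if nr != len(self.classes) or nc != len(self.classes) + 1:
            raise ValueError("fold_counts shape does not match class list")

    @property
    def outcomes(self) -> list[str]:
        return [*self.classes, OTHERS]

    @property
    def n_folds(self) -> int:
        return self.fold_counts.shape[0]

    @property
    def combined(self) -> np.ndarray:
        return self.fold_counts.sum(axis=0)

    @property
    def n_per_class(self) -> np.ndarray:
        return self.combined.sum(axis=1)

    @property
    def tp_per_class(self) -> np.ndarray:
        return np.diagonal(self.combined)

    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """Row-normalized per-fold matrices: (mean, sd) over folds."""
        mats = self.fold_counts.astype(float)
        sums = mats.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(sums > 0, mats / sums, np.nan)
        return np.nanmean(norm, axis=0), np.nanstd(norm, axis=0)

    def sacc_per_fold(self) -> np.ndarray:
        tp = np.diagonal(self.fold_counts, axis1=1, axis2=2).sum(axis=1)
        tot = self.fold_counts.sum(axis=(1, 2))
        return tp / tot

    def to_frame(self, which: str = "combined") -> pd.DataFrame:
        if which == "combined":
            data = self.combined
        else:
            data = self.normalized()[0]
        return pd.DataFrame(data, index=self.classes, columns=self.outcomes)


def sacc(counts: np.ndarray | ConfusionSummary, classes: list[str] | None = None) -> float:
    """Dataset-level accuracy: exact-label true positives over all samples."""
    if isinstance(counts, ConfusionSummary):
        mat = counts.combined
    else:
        mat = np.asarray(counts, dtype=float)
    if classes is not None and len(classes) == 0:
        raise ValueError("class list must be non-empty")
    if mat.size == 0 or mat.sum() == 0:
        raise ValueError("empty confusion counts")
    return float(np.diagonal(mat).sum() / mat.sum())


def confusion_counts(
    observed: list[str], predicted: list[str], classes: list[str]
) -> np.ndarray:
    """(|L|, |L|+1) counts: rows observed classes, columns outcomes."""
    outcomes = [*classes, OTHERS]
    col = {name: j for j, name in enumerate(outcomes)}
    mat = np.zeros((len(classes), len(outcomes)), dtype=int)
    row = {name: i for i, name in enumerate(classes)}
    for obs, pred in zip(observed, predicted):
        mat[row[obs], col.get(pred, len(outcomes) - 1)] += 1
    return mat


def per_class_metrics(summary: ConfusionSummary) -> pd.DataFrame:
    """Accuracy, recall, precision, specificity per class.

    For class i the diagonal element is TP, the rest of column i is FP, the
    rest of row i (including ``Others``) is FN and everything else is TN.
    Metrics are computed per fold and averaged; folds where a ratio is 0/0
    are excluded from that metric's average, and the number of folds used
    is reported.
    """
    rows = []
    for i, cls in enumerate(summary.classes):
        per_fold: dict[str, list[float]] = {m: [] for m in ("accuracy", "recall", "precision", "specificity")}
        for mat in summary.fold_counts:
            total = mat.sum()
            tp = mat[i, i]
            fp = mat[:, i].sum() - tp
            fn = mat[i, :].sum() - tp
            tn = total - tp - fp - fn
            per_fold["accuracy"].append((tp + tn) / total if total else np.nan)
            per_fold["recall"].append(tp / (tp + fn) if tp + fn else np.nan)
            per_fold["precision"].append(tp / (tp + fp) if tp + fp else np.nan)
            per_fold["specificity"].append(tn / (tn + fp) if tn + fp else np.nan)
        row: dict = {"class": cls}
        for metric, vals in per_fold.items():
            arr = np.array(vals, dtype=float)
            ok = np.isfinite(arr)
            row[metric] = float(arr[ok].mean()) if ok.any() else np.nan
            row[f"{metric}_sd"] = float(arr[ok].std()) if ok.any() else np.nan
            row[f"{metric}_folds"] = int(ok.sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Everything a completed cross-validation run produced."""

    scheme: str
    classes: list[str]
    fold_assignment: np.ndarray
    fold_models: list[nn.Network]
    predictions: np.ndarray  # (m, output_dim) 0/1, each sample from its test fold
    predicted_classes: list[str]
    observed_classes: list[str]
    summary: ConfusionSummary
    loss_histories: list[list[float]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.fold_models)

    def sacc_mean_sd(self) -> tuple[float, float]:
        per_fold = self.summary.sacc_per_fold()
        return float(per_fold.mean()), float(per_fold.std())


def cross_validate(
    X: np.ndarray,
    observed_classes: list[str],
    scheme: str,
    config: TrainConfig,
    k: int = 5,
    conv_channels: tuple[int, int, int] = (64, 128, 128),
    classes: list[str] | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the pocket classifier.

    Each sample is predicted exactly once, by the model of the fold that
    holds it out.  Raises when any class has fewer than ``k`` samples.
    """
    from .function import encode_labels

    X = np.asarray(X, dtype=nn.F4)
    m = len(X)
    if m != len(observed_classes):
        raise ValueError("X and observed_classes length mismatch")
    classes = classes or [c for c in scheme_classes(scheme) if c in set(observed_classes)]
    Y = np.array([encode_labels(c, scheme) for c in observed_classes], dtype=nn.F4)
    out_dim = Y.shape[1]
    assignment = stratified_folds(observed_classes, k, seed=config.seed)

    fold_models: list[nn.Network] = []
    loss_histories: list[list[float]] = []
    predictions = np.zeros((m, out_dim), dtype=int)
    fold_counts = np.zeros((k, len(classes), len(classes) + 1), dtype=int)
    predicted_classes = [""] * m
    n_edge = X.shape[2]
    for fold in range(k):
        test = np.where(assignment == fold)[0]
        tr = np.where(assignment != fold)[0]
        model = nn.build_network(
            n_edge, out_dim, seed=config.seed * 1000 + fold, conv_channels=conv_channels
        )
        fold_config = TrainConfig(
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            epochs=config.epochs,
            seed=config.seed * 1000 + fold,
        )
        loss_histories.append(train(model, X[tr], Y[tr], fold_config))
        preds = predict_labels(model, X[test])
        predictions[test] = preds
        pred_names = [decode_labels(p, scheme) for p in preds]
        for i, name in zip(test, pred_names):
            predicted_classes[i] = name
        fold_counts[fold] = confusion_counts(
            [observed_classes[i] for i in test], pred_names, classes
        )
        fold_models.append(model)

    summary = ConfusionSummary(classes=classes, fold_counts=fold_counts)
    return CVResult(
        scheme=scheme,
        classes=classes,
        fold_assignment=assignment,
        fold_models=fold_models,
        predictions=predictions,
        predicted_classes=predicted_classes,
        observed_classes=list(observed_classes),
        summary=summary,
        loss_histories=loss_histories,
    )


# ---------------------------------------------------------------------------
# run persistence (for the command-line workflow)
# ---------------------------------------------------------------------------

def save_run(run: CVResult, out_dir) -> None:
    """Persist a cross-validation run: manifest, folds and model weights."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mean, sd = run.sacc_mean_sd()
    manifest = {
        "scheme": run.scheme,
        "classes": run.classes,
        "observed_classes": run.observed_classes,
        "k": run.k,
        "sacc_mean": mean,
        "sacc_sd": sd,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    np.save(out / "fold_assignment.npy", run.fold_assignment)
    np.save(out / "predictions.npy", run.predictions)
    for i, model in enumerate(run.fold_models):
        model.save(out / f"fold{i}.npz")
    run.summary.to_frame("combined").to_csv(out / "confusion_combined.csv")
    norm_mean, norm_sd = run.summary.normalized()
    pd.DataFrame(norm_mean, index=run.classes, columns=run.summary.outcomes).to_csv(
        out / "confusion_normalized_mean.csv"
    )
    per_class_metrics(run.summary).to_csv(out / "metrics.csv")


def load_run(out_dir) -> CVResult:
    """Reload a saved run with enough state to re-score predictions."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    assignment = np.load(out / "fold_assignment.npy")
    predictions = np.load(out / "predictions.npy")
    models = [nn.Network.load(out / f"fold{i}.npz") for i in range(manifest["k"])]
    observed = manifest["observed_classes"]
    classes = manifest["classes"]
    predicted = [decode_labels(p, manifest["scheme"]) for p in predictions]
    fold_counts = np.stack(
        [
            confusion_counts(
                [observed[i] for i in np.where(assignment == f)[0]],
                [predicted[i] for i in np.where(assignment == f)[0]],
                classes,
            )
            for f in range(manifest["k"])
        ]
    )
    return CVResult(
        scheme=manifest["scheme"],
        classes=classes,
        fold_assignment=assignment,
        fold_models=models,
        predictions=predictions,
        predicted_classes=predicted,
        observed_classes=observed,
        summary=ConfusionSummary(classes=classes, fold_counts=fold_counts),
    )
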