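"""Cross-validated training and evaluation of the four-stream classifier.

The protocol is k-fold (default 3) cross-validation grouped by source clip:
all windows of one clip land on the same side of every split, so the test
folds never share footage with training. Per fold, the test set receives at
most floor(N/k) samples (whole clips), and the remainder is split ~90/10
into training and validation; the checkpoint with the best validation
accuracy is used for testing.

Metrics come from the 4x4 confusion matrix: accuracy is the fraction of
correctly classified test samples; sensitivity, specificity and precision
are one-vs-rest per class and macro-averaged. ROC curves are one-vs-rest
per class on the softmax scores. Information density is accuracy (%)
divided by the learnable-parameter count in millions — a parameter-
efficiency score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc

from . import nn
from .model_4s3dcnn import ConfigurationError, FourStreamNet, ModelConfig, build_model
from .video_io import PHASES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the reference protocol (Adam, learning rate 0.001, L2
    0.0001, 100 epochs, minibatch 8); desk-scale runs shrink ``epochs`` and
    the dataset, not the architecture.
    """

    learning_rate: float = 0.001
    l2_regularization: float = 0.0001
    epochs: int = 100
    minibatch: int = 8
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    val_fraction: float = 0.1

    def __post_init__(self):
        if min(self.learning_rate, self.epochs, self.minibatch) <= 0:
            raise ValueError("learning_rate, epochs and minibatch must be positive")
        if self.l2_regularization < 0:
            raise ValueError("l2_regularization must be >= 0")


@dataclass(frozen=True)
class FoldSplit:
    """Index sets of one cross-validation fold (indices into the sample set)."""

    fold_index: int
    test_idx: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray


def _clip_ids_of(records) -> np.ndarray:
    if hasattr(records[0], "clip_id"):
        return np.asarray([r.clip_id for r in records])
    return np.asarray(records)


def make_folds(records: Sequence, k: int = 3, seed: int = 0, val_fraction: float = 0.1) -> list[FoldSplit]:
    """Clip-grouped k-fold splits.

    ``records`` is a sequence of sample records (anything with a ``clip_id``
    attribute) or plain clip-id strings, one per sample. Clips are shuffled
    deterministically, partitioned into k groups balanced by window count,
    and each group in turn provides the test set — trimmed to at most
    floor(N/k) samples by moving whole clips to that fold's training side.
    The remainder is split ~(1-val_fraction)/val_fraction into train and
    validation, again by whole clips.
    """
    records = list(records)
    n = len(records)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    clip_ids = _clip_ids_of(records)
    rng = np.random.default_rng(seed)
    unique, counts = np.unique(clip_ids, return_counts=True)
    order = rng.permutation(len(unique))
    # largest-first balanced assignment into k groups (stable tie-breaks)
    by_size = sorted(order, key=lambda i: -counts[i])
    group_of = {}
    totals = [0] * k
    for i in by_size:
        g = int(np.argmin(totals))
        group_of[unique[i]] = g
        totals[g] += counts[i]
    idx_of_clip = {c: np.flatnonzero(clip_ids == c) for c in unique}
    target_test = n // k
    folds = []
    for f in range(k):
        test_clips = [c for c in unique[order] if group_of[c] == f]
        extra_train: list = []
        test_count = sum(len(idx_of_clip[c]) for c in test_clips)
        while test_count > target_test and test_clips:
            smallest = min(test_clips, key=lambda c: len(idx_of_clip[c]))
            test_clips.remove(smallest)
            extra_train.append(smallest)
            test_count -= len(idx_of_clip[smallest])
        rest = [c for c in unique[order] if group_of[c] != f] + extra_train
        rest = [rest[i] for i in rng.permutation(len(rest))]
        n_rest = sum(len(idx_of_clip[c]) for c in rest)
        target_val = int(val_fraction * n_rest)
        val_clips, val_count = [], 0
        for c in rest:
            if val_count >= target_val:
                break
            val_clips.append(c)
            val_count += len(idx_of_clip[c])
        train_clips = [c for c in rest if c not in set(val_clips)]
        cat = lambda clips: (
            np.concatenate([idx_of_clip[c] for c in clips])
            if clips
            else np.empty(0, dtype=int)
        )
        folds.append(
            FoldSplit(
                fold_index=f + 1,
                test_idx=np.sort(cat(test_clips)),
                train_idx=np.sort(cat(train_clips)),
                val_idx=np.sort(cat(val_clips)),
            )
        )
    return folds


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionMetrics:
    """Macro metrics (in %) derived from a square confusion matrix."""

    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    per_class: dict


def compute_metrics(confusion: np.ndarray) -> ConfusionMetrics:
    """Accuracy and macro one-vs-rest sensitivity/specificity/precision.

    Accuracy is the correctly classified fraction (trace / total). The other
    three are computed per class from TP/TN/FP/FN and macro-averaged;
    classes with an undefined ratio (zero denominator) are excluded from the
    macro mean with a warning.
    """
    m = np.asarray(confusion, dtype=np.int64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {m.shape}")
    if (m < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for c in range(m.shape[0]):
        tp = m[c, c]
        fn = m[c].sum() - tp
        fp = m[:, c].sum() - tp
        tn = total - tp - fn - fp
        per_class[c] = {
            "sensitivity": _ratio(tp, tp + fn, f"class {c} sensitivity"),
            "specificity": _ratio(tn, tn + fp, f"class {c} specificity"),
            "precision": _ratio(tp, tp + fp, f"class {c} precision"),
        }
    macro = {
        key: float(np.nanmean([per_class[c][key] for c in per_class]))
        for key in ("sensitivity", "specificity", "precision")
    }
    return ConfusionMetrics(
        confusion=m,
        accuracy=100.0 * float(np.trace(m)) / float(total),
        sensitivity=macro["sensitivity"],
        specificity=macro["specificity"],
        precision=macro["precision"],
        per_class=per_class,
    )


def _ratio(num, den, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); excluded from macro mean")
        return float("nan")
    return 100.0 * float(num) / float(den)


def information_density(accuracy_pct: float, params_millions: float) -> float:
    """Accuracy (%) divided by parameter count in millions."""
    if params_millions <= 0:
        raise ValueError("params_millions must be > 0")
    return accuracy_pct / params_millions


@dataclass
class FoldMetrics:
    fold_index: int
    n_test: int
    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    roc: dict  # class index -> (fpr, tpr, thresholds)
    auc: dict  # class index -> float
    history: list


@dataclass
class MetricsReport:
    """Per-fold and aggregate cross-validation results."""

    folds: list[FoldMetrics]
    mean: dict
    std: dict
    information_density: Optional[float] = None

    METRICS = ("accuracy", "sensitivity", "specificity", "precision")

    @classmethod
    def from_folds(cls, folds: list[FoldMetrics], params_m: Optional[float] = None):
        mean = {k: float(np.mean([getattr(f, k) for f in folds])) for k in cls.METRICS}
        std = {k: float(np.std([getattr(f, k) for f in folds])) for k in cls.METRICS}
        dens = (
            information_density(mean["accuracy"], params_m) if params_m is not None else None
        )
        return cls(folds=folds, mean=mean, std=std, information_density=dens)

    def to_frame(self):
        """Per-fold + mean/std metrics as a pandas DataFrame."""
        import pandas as pd

        rows = [
            {"fold": f.fold_index, **{k: getattr(f, k) for k in self.METRICS}}
            for f in self.folds
        ]
        rows.append({"fold": "mean", **self.mean})
        rows.append({"fold": "std", **self.std})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def plot_roc(report: MetricsReport, path) -> None:
    """One-vs-rest ROC curves of every fold, one panel per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(PHASES), figsize=(4 * len(PHASES), 3.5), sharey=True)
    for c, ax in enumerate(np.atleast_1d(axes)):
        for f in report.folds:
            fpr, tpr, _ = f.roc[c]
            ax.plot(fpr, tpr, label=f"fold {f.fold_index} (AUC {f.auc[c]:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_title(PHASES[c])
        ax.set_xlabel("false positive rate")
        ax.legend(fontsize=7)
    np.atleast_1d(axes)[0].set_ylabel("true positive rate")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# training


def _predict_proba_batched(net: FourStreamNet, X: np.ndarray, batch: int = 32) -> np.ndarray:
    out = [net.predict_proba(X[i : i + batch]) for i in range(0, len(X), batch)]
    return np.concatenate(out, axis=0)


def train_network(
    net: FourStreamNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: Optional[np.ndarray],
    y_val: Optional[np.ndarray],
    cfg: TrainConfig,
) -> list[dict]:
    """Minibatch Adam training with best-validation-accuracy checkpointing.

    Returns the per-epoch history (loss, training accuracy, validation
    accuracy); the network is left holding the checkpointed parameters.
    """
    opt = nn.Adam(
        net.params(),
        lr=cfg.learning_rate,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        l2=cfg.l2_regularization,
    )
    rng = np.random.default_rng(cfg.seed)
    history = []
    best = (-1.0, None)
    have_val = X_val is not None and len(X_val) > 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(X_train))
        losses, correct = [], 0
        for start in range(0, len(perm), cfg.minibatch):
            idx = perm[start : start + cfg.minibatch]
            logits = net.forward(X_train[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_train[idx])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=-1) == y_train[idx]).sum())
        entry = {
            "epoch": epoch + 1,
            "loss": float(np.mean(losses)),
            "train_acc": 100.0 * correct / len(X_train),
        }
        if have_val:
            val_pred = _predict_proba_batched(net, X_val).argmax(axis=-1)
            entry["val_acc"] = 100.0 * float((val_pred == y_val).mean())
            if entry["val_acc"] >= best[0]:
                best = (entry["val_acc"], net.state_copy())
        history.append(entry)
        logger.info(
            "epoch %d/%d loss %.4f train %.1f%%%s",
            epoch + 1,
            cfg.epochs,
            entry["loss"],
            entry["train_acc"],
            f" val {entry.get('val_acc', float('nan')):.1f}%" if have_val else "",
        )
    if best[1] is not None:
        net.load_state(best[1])
    return history


def evaluate_fold(
    net: FourStreamNet, X_test: np.ndarray, y_test: np.ndarray, fold_index: int = 1, history=None
) -> FoldMetrics:
    """Confusion matrix, macro metrics and per-class ROC on a test set."""
    probs = _predict_proba_batched(net, X_test)
    preds = probs.argmax(axis=-1)
    n_classes = net.config.n_classes
    confusion = _sk_confusion(y_test, preds, labels=list(range(n_classes)))
    cm = compute_metrics(confusion)
    roc, aucs = {}, {}
    for c in range(n_classes):
        if (y_test == c).any() and (y_test != c).any():
            fpr, tpr, thr = _sk_roc(y_test == c, probs[:, c])
        else:  # degenerate test composition: no curve
            fpr, tpr, thr = np.array([0.0, 1.0]), np.array([0.0, 1.0]), np.array([np.inf, 0.0])
        roc[c] = (fpr, tpr, thr)
        aucs[c] = float(_sk_auc(fpr, tpr))
    return FoldMetrics(
        fold_index=fold_index,
        n_test=len(y_test),
        confusion=confusion,
        accuracy=cm.accuracy,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        precision=cm.precision,
        roc=roc,
        auc=aucs,
        history=history or [],
    )


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    clip_ids: Sequence[str],
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    k: int = 3,
) -> MetricsReport:
    """Full k-fold cross-validated training and evaluation.

    One fresh network per fold (seed = ``train_cfg.seed`` + fold index);
    raises :class:`ConfigurationError` if any fold's training set is missing
    a class.
    """
    folds = make_folds(
        list(clip_ids), k=k, seed=train_cfg.seed, val_fraction=train_cfg.val_fraction
    )
    n_classes = model_cfg.n_classes
    for split in folds:
        present = set(np.unique(y[split.train_idx]).tolist())
        if present != set(range(n_classes)):
            missing = sorted(set(range(n_classes)) - present)
            raise ConfigurationError(
                f"fold {split.fold_index} training set is missing class(es) {missing}; "
                "provide more clips per class"
            )
    results = []
    for split in folds:
        fold_seed = train_cfg.seed + split.fold_index
        net = FourStreamNet(model_cfg, seed=fold_seed)
        fold_train = TrainConfig(
            learning_rate=train_cfg.learning_rate,
            l2_regularization=train_cfg.l2_regularization,
            epochs=train_cfg.epochs,
            minibatch=train_cfg.minibatch,
            seed=fold_seed,
            beta1=train_cfg.beta1,
            beta2=train_cfg.beta2,
            val_fraction=train_cfg.val_fraction,
        )
        logger.info(
            "fold %d: train %d / val %d / test %d",
            split.fold_index,
            len(split.train_idx),
            len(split.val_idx),
            len(split.test_idx),
        )
        history = train_network(
            net,
            X[split.train_idx],
            y[split.train_idx],
            X[split.val_idx] if len(split.val_idx) else None,
            y[split.val_idx] if len(split.val_idx) else None,
            fold_train,
        )
        results.append(
            evaluate_fold(net, X[split.test_idx], y[split.test_idx], split.fold_index, history)
        )
    # exact millions (not truncated) so small desk-scale models keep a
    # meaningful density score
    return MetricsReport.from_folds(results, params_m=build_model(model_cfg).total_params / 1e6)
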