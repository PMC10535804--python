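"""Training, splitting, fivefold cross-validation, metrics and reports.

Training minimises binary cross-entropy with Adam (initial learning rate
1e-4, minibatches of 128) and early stopping on validation loss with
patience 3, restoring the best-validation weights. Evaluation follows the
windowed protocol: a stratified 70/30 train/test split, fivefold stratified
cross-validation on the training portion, and accuracy / precision /
recall / specificity / F1 / AUC per fold.

The default split unit is the window, mirroring the original protocol;
note that windows from one subject can then appear on both sides of a
split, which inflates metrics on subject-correlated data. A subject-level
split (``split_unit='subject'``) is available and recommended when the
question is generalisation to unseen people.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import FeatureWindow, standardize, to_arrays
from .model import BiLSTMAttentionClassifier, ModelSpec, build_model

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 100
    early_stop_patience: int = 3
    test_fraction: float = 0.3
    folds: int = 5
    split_unit: str = "window"
    stratify: bool = True
    standardize: bool = True
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.split_unit not in ("window", "subject"):
            raise ValueError("split_unit must be 'window' or 'subject'")


@dataclass
class FoldMetrics:
    """Per-fold evaluation record: confusion counts, the derived metrics,
    AUC and per-epoch loss/accuracy traces."""

    fold_index: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float = float("nan")
    undefined: list[str] = field(default_factory=list)
    loss_trace: dict = field(default_factory=dict)
    acc_trace: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# loss / optimiser


def bce_loss(y_true: np.ndarray, y_prob: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(y_prob, eps, 1.0 - eps)
    return float(-np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))


class Adam:
    """Standard Adam over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


# ---------------------------------------------------------------------------
# splitting


def _stratified_indices(
    y: np.ndarray, test_total: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Largest-remainder per-class allocation of exactly ``test_total``
    test samples, sampled without replacement within class."""
    classes, counts = np.unique(y, return_counts=True)
    quotas = counts * test_total / counts.sum()
    base = np.floor(quotas).astype(int)
    rem = quotas - base
    short = test_total - base.sum()
    for j in np.argsort(-rem)[:short]:
        base[j] += 1
    test_idx = []
    for cls, k in zip(classes, base):
        members = np.flatnonzero(y == cls)
        test_idx.append(rng.choice(members, size=k, replace=False))
    test_idx = np.sort(np.concatenate(test_idx))
    mask = np.ones(len(y), dtype=bool)
    mask[test_idx] = False
    return np.flatnonzero(mask), test_idx


def split_train_test(
    windows: list[FeatureWindow], cfg: TrainConfig
) -> tuple[list[FeatureWindow], list[FeatureWindow]]:
    """Stratified train/test split with |test| = round(test_fraction * n).

    split_unit='window' assigns windows independently (the original
    protocol); split_unit='subject' keeps each subject entirely on one side
    and greedily matches the requested window-count fraction.
    """
    y = np.array([w.label for w in windows])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present before splitting")
    rng = np.random.default_rng(cfg.seed)
    if cfg.split_unit == "window":
        n_test = int(round(cfg.test_fraction * len(windows)))
        if cfg.stratify:
            train_idx, test_idx = _stratified_indices(y, n_test, rng)
        else:
            perm = rng.permutation(len(windows))
            test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
        return [windows[i] for i in train_idx], [windows[i] for i in test_idx]

    # subject-level: greedy fill of the test side, per class for balance
    by_subject: dict[str, list[int]] = {}
    subj_label: dict[str, int] = {}
    for i, w in enumerate(windows):
        by_subject.setdefault(w.subject_id, []).append(i)
        subj_label[w.subject_id] = w.label
    target = cfg.test_fraction * len(windows)
    test_subjects: set[str] = set()
    filled = 0
    for cls in (0, 1):
        subs = [s for s in by_subject if subj_label[s] == cls]
        rng.shuffle(subs)
        cls_total = sum(len(by_subject[s]) for s in subs)
        cls_target = cfg.test_fraction * cls_total
        cls_filled = 0
        for s in subs:
            if cls_filled >= cls_target:
                break
            test_subjects.add(s)
            cls_filled += len(by_subject[s])
        filled += cls_filled
    train = [w for w in windows if w.subject_id not in test_subjects]
    test = [w for w in windows if w.subject_id in test_subjects]
    if not train or not test:
        raise ValueError("subject split produced an empty side; too few subjects")
    return train, test


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5,
    fold_index: int = 0,
) -> FoldMetrics:
    """Confusion counts at ``threshold`` and the five derived metrics.

    Zero-denominator ratios are reported as 0 and flagged in ``undefined``.
    """
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have the same length")
    y_pred = (y_prob >= threshold).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, tp + fp + tn + fn, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    if precision + recall == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return FoldMetrics(
        fold_index=fold_index, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, precision=precision, recall=recall,
        specificity=specificity, f1=f1, undefined=undefined,
    )


def roc_auc(y_true: np.ndarray, y_prob: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep over the unique probabilities; trapezoid AUC.

    Returns (fpr, tpr, auc). Equals the normalised Mann–Whitney U statistic.
    """
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-y_prob, kind="stable")
    y_sorted = y_true[order]
    p_sorted = y_prob[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last point of each tied-probability run
    keep = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def early_stop_epoch(val_losses: list[float], patience: int) -> int | None:
    """Index (0-based) of the epoch after which training stops, or None.

    Training halts once ``patience`` consecutive epochs fail to improve on
    the running validation-loss minimum.
    """
    best = np.inf
    since = 0
    for i, v in enumerate(val_losses):
        if v < best:
            best = v
            since = 0
        else:
            since += 1
            if since >= patience:
                return i
    return None


def train_model(
    X_train: np.ndarray, y_train: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[BiLSTMAttentionClassifier, TrainHistory]:
    """Minibatch Adam/BCE training with early stopping on validation loss;
    the best-validation weights are restored before returning."""
    cfg = cfg or TrainConfig()
    model = build_model(spec, seed=cfg.seed)
    params = [p for p, _ in _model_params(model)]
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    hist = TrainHistory()
    best_val = np.inf
    best_weights: list[np.ndarray] | None = None
    since = 0
    n = len(X_train)
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        batch_losses: list[float] = []
        batch_accs: list[float] = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            Xb, yb = X_train[idx], y_train[idx]
            p = model.forward(Xb, train=True)
            batch_losses.append(bce_loss(yb, p) * len(yb))
            batch_accs.append(float(np.sum((p >= cfg.threshold) == yb)))
            dz = (p - yb) / len(yb)  # d(BCE)/d(logit)
            model.backward(dz)
            grads = [g for _, g in model.params_and_grads()]
            opt.step(grads)
        p_va = model.predict_proba(X_val)
        # train trace = running minibatch average (avoids a second full pass)
        tr_loss, va_loss = sum(batch_losses) / n, bce_loss(y_val, p_va)
        hist.train_loss.append(tr_loss)
        hist.val_loss.append(va_loss)
        hist.train_acc.append(sum(batch_accs) / n)
        hist.val_acc.append(float(np.mean((p_va >= cfg.threshold) == y_val)))
        if not np.isfinite(va_loss) or not np.isfinite(tr_loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: train={tr_loss}, val={va_loss}"
            )
        if va_loss < best_val:
            best_val = va_loss
            best_weights = [p.copy() for p in params]
            hist.best_epoch = epoch
            since = 0
        else:
            since += 1
            if since >= cfg.early_stop_patience:
                break
    hist.stopped_epoch = epoch
    if best_weights is not None:
        for p, w in zip(params, best_weights):
            p[...] = w
    return model, hist


def _model_params(model: BiLSTMAttentionClassifier) -> list[tuple[np.ndarray, None]]:
    out = []
    for layer in model.layers:
        out += [(layer.fwd.W_x, None), (layer.fwd.W_h, None), (layer.fwd.b, None),
                (layer.bwd.W_x, None), (layer.bwd.W_h, None), (layer.bwd.b, None)]
    out += [(model.W_out, None), (model.b_out, None)]
    return out


# ---------------------------------------------------------------------------
# cross-validation and grid search


def crossvalidate(
    train_windows: list[FeatureWindow],
    spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
) -> list[FoldMetrics]:
    """Stratified k-fold CV on the training portion.

    Each fold trains a fresh model (early stopping, best weights restored)
    and is scored on its validation fold. Standardisation statistics are
    fitted on each fold's training part only.
    """
    cfg = cfg or TrainConfig()
    X, y = to_arrays(train_windows)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < cfg.folds:
        raise ValueError("each class needs at least `folds` windows")
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    folds: list[FoldMetrics] = []
    for k, (tr, va) in enumerate(skf.split(X, y)):
        Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]
        if cfg.standardize:
            Xtr, mu, sd = standardize(Xtr)
            Xva, _, _ = standardize(Xva, mu, sd)
        model, hist = train_model(Xtr, ytr, Xva, yva, spec, cfg)
        p_va = model.predict_proba(Xva)
        fm = compute_metrics(yva, p_va, cfg.threshold, fold_index=k)
        _, _, fm.auc = roc_auc(yva, p_va)
        fm.loss_trace = {"train": hist.train_loss, "val": hist.val_loss}
        fm.acc_trace = {"train": hist.train_acc, "val": hist.val_acc}
        folds.append(fm)
        logger.info("fold %d: acc=%.3f auc=%.3f (epochs=%d)",
                    k, fm.accuracy, fm.auc, hist.stopped_epoch + 1)
    return folds


_GRID_TARGETS = {
    "learning_rate": "cfg", "batch_size": "cfg", "max_epochs": "cfg",
    "early_stop_patience": "cfg", "threshold": "cfg",
    "bilstm_units": "spec", "dropout_rates": "spec",
}


def grid_search(
    train_windows: list[FeatureWindow],
    spec: ModelSpec | None = None,
    grid: dict[str, list] | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[dict, list[dict]]:
    """Exhaustive CV over the cartesian hyperparameter grid.

    Best = highest mean validation accuracy, ties broken by lower mean
    validation loss. Returns (best config dict, full results table).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    spec = spec or ModelSpec()
    cfg = cfg or TrainConfig()
    for name in grid:
        if name not in _GRID_TARGETS:
            raise KeyError(
                f"unknown hyperparameter {name!r}; searchable: "
                f"{', '.join(sorted(_GRID_TARGETS))}"
            )
    names = list(grid)
    table: list[dict] = []
    best_row: dict | None = None
    for values in itertools.product(*(grid[n] for n in names)):
        assign = dict(zip(names, values))
        cfg_i = dataclasses.replace(
            cfg, **{k: v for k, v in assign.items() if _GRID_TARGETS[k] == "cfg"}
        )
        spec_kwargs = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in assign.items() if _GRID_TARGETS[k] == "spec"}
        spec_i = dataclasses.replace(spec, **spec_kwargs)
        folds = crossvalidate(train_windows, spec_i, cfg_i)
        mean_acc = float(np.mean([f.accuracy for f in folds]))
        mean_loss = float(np.mean([f.loss_trace["val"][-1] for f in folds]))
        row = {"params": assign, "mean_val_accuracy": mean_acc,
               "mean_val_loss": mean_loss,
               "fold_accuracies": [f.accuracy for f in folds]}
        table.append(row)
        if (best_row is None
                or mean_acc > best_row["mean_val_accuracy"]
                or (mean_acc == best_row["mean_val_accuracy"]
                    and mean_loss < best_row["mean_val_loss"])):
            best_row = row
    return best_row, table


# ---------------------------------------------------------------------------
# reporting


def aggregate_metrics(folds: list[FoldMetrics]) -> dict:
    names = ("accuracy", "precision", "recall", "specificity", "f1", "auc")
    agg = {}
    for name in names:
        vals = np.array([getattr(f, name) for f in folds], dtype=float)
        agg[name] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=0))}
    return agg


def export_report(folds: list[FoldMetrics], outdir: str | Path,
                  roc_data: list[tuple[np.ndarray, np.ndarray]] | None = None
                  ) -> dict[str, Path]:
    """Write metrics.json plus accuracy/loss curves, box plots and (when ROC
    point data are provided) the per-fold ROC figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    payload = {"folds": [f.to_dict() for f in folds],
               "aggregate": aggregate_metrics(folds)}
    mpath = outdir / "metrics.json"
    mpath.write_text(json.dumps(payload, indent=2))
    written["metrics"] = mpath

    for key, title in (("acc_trace", "accuracy"), ("loss_trace", "loss")):
        fig, ax = plt.subplots(figsize=(7, 4))
        for f in folds:
            trace = getattr(f, key)
            if not trace:
                continue
            epochs = np.arange(1, len(trace["train"]) + 1)
            ax.plot(epochs, trace["train"], label=f"fold {f.fold_index} train")
            ax.plot(epochs, trace["val"], "--", label=f"fold {f.fold_index} val")
        ax.set_xlabel("epoch")
        ax.set_ylabel(title)
        ax.set_title(f"training/validation {title} per fold")
        if ax.get_legend_handles_labels()[0]:
            ax.legend(fontsize=6, ncol=2)
        p = outdir / f"{title}_curves.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written[f"{title}_curves"] = p

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    final_losses = [f.loss_trace["val"][-1] if f.loss_trace else np.nan for f in folds]
    axes[0].boxplot([final_losses], tick_labels=["val loss"])
    axes[1].boxplot([[f.accuracy for f in folds]], tick_labels=["val accuracy"])
    for ax in axes:
        ax.set_title("across folds")
    p = outdir / "fold_boxplots.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written["boxplots"] = p

    if roc_data is not None:
        fig, ax = plt.subplots(figsize=(5, 5))
        for f, (fpr, tpr) in zip(folds, roc_data):
            ax.plot(fpr, tpr, label=f"fold {f.fold_index} (AUC={f.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        p = outdir / "roc_curves.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written["roc"] = p
    return written
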