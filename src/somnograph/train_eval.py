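"""Training loop, subject-wise cross-validation, and scoring metrics.

Training follows the reference recipe: Adam, batch size 64, initial
learning rate 1e-3 divided by 10 at epochs 30/60/90, dropout 0.2, 120
epochs.  Evaluation computes the standard sleep-scoring metric suite
from a 5×5 confusion matrix (rows = actual stage, columns = predicted,
order W/N1/N2/N3/R): accuracy, per-class precision/recall/F1,
macro-averages, and Cohen's kappa κ = (p_o − p_e)/(1 − p_e).

The macro-F score is reported as the unweighted mean of per-class F1
(the convention under which published per-class rows and macro rows are
mutually consistent); the harmonic combination of macro-precision and
macro-recall is also exposed as ``macro_f_harmonic``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor
from .network import STAGES, SleepStageNetwork

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalReport",
    "subject_folds",
    "learning_rate_at",
    "train",
    "confusion",
    "evaluate",
    "read_confusion_tsv",
    "write_confusion_tsv",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (reference defaults)."""

    batch_size: int = 64
    epochs: int = 120
    lr: float = 1e-3
    lr_step_epochs: tuple[int, ...] = (30, 60, 90)
    lr_decay: float = 10.0
    seed: int = 0
    class_weighting: str = "none"  # "none" or "inverse"

    def __post_init__(self) -> None:
        steps = tuple(int(e) for e in self.lr_step_epochs)
        if list(steps) != sorted(steps):
            raise ValueError("lr step epochs must be ascending")
        if steps and steps[-1] >= self.epochs:
            warnings.warn("lr step epochs beyond the training horizon",
                          stacklevel=2)
        self.lr_step_epochs = steps
        if self.class_weighting not in ("none", "inverse"):
            raise ValueError("class_weighting must be 'none' or 'inverse'")


def learning_rate_at(epoch: int, cfg: TrainConfig) -> float:
    """Stepped schedule: lr / decay^(number of step epochs passed)."""
    n_steps = sum(1 for s in cfg.lr_step_epochs if epoch >= s)
    return cfg.lr / (cfg.lr_decay ** n_steps)


def subject_folds(subject_ids, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-wise cross-validation folds over per-sample subject ids.

    Unique subjects (in order of first appearance) are partitioned into
    ``k`` test groups — one subject per fold when ``k`` equals the
    subject count (leave-one-subject-out).  Returns (train_idx, test_idx)
    index arrays per fold.
    """
    subject_ids = np.asarray(subject_ids)
    _, first = np.unique(subject_ids, return_index=True)
    unique = subject_ids[np.sort(first)]
    if k < 1 or k > len(unique):
        raise ValueError(f"k={k} folds for {len(unique)} subjects")
    groups = np.array_split(unique, k)
    folds = []
    for group in groups:
        test_mask = np.isin(subject_ids, group)
        folds.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return folds


@dataclass
class TrainResult:
    loss_trace: list[float]
    lr_trace: list[float]
    final_train_accuracy: float


def _batch_loss(model: SleepStageNetwork, xb: np.ndarray, yb: np.ndarray,
                weights: np.ndarray | None,
                rng: np.random.Generator) -> tuple[Tensor, np.ndarray]:
    logits = model.forward(xb, training=True, rng=rng)
    log_probs = logits.log_softmax(axis=-1)
    picked = log_probs[np.arange(len(yb)), yb]
    if weights is None:
        loss = -picked.mean()
    else:
        wv = weights[yb]
        loss = -(picked * Tensor(wv)).sum() * (1.0 / float(wv.sum()))
    return loss, np.argmax(logits.data, axis=-1)


def train(model: SleepStageNetwork, x: np.ndarray, y: np.ndarray,
          cfg: TrainConfig | None = None) -> TrainResult:
    """Train in place; returns per-epoch loss and learning-rate traces.

    ``x`` is (samples, bands, context_len, electrodes); ``y`` holds
    integer stage ids.  A non-finite loss aborts with a diagnostic.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(x) < 1:
        raise ValueError("need at least one training sample")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    weights = None
    if cfg.class_weighting == "inverse":
        counts = np.bincount(y, minlength=model.config.n_classes)
        weights = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        weights = weights / weights.sum() * model.config.n_classes
    loss_trace: list[float] = []
    lr_trace: list[float] = []
    last_preds = np.empty(0, dtype=int)
    last_targets = np.empty(0, dtype=int)
    for epoch in range(cfg.epochs):
        opt.lr = learning_rate_at(epoch, cfg)
        lr_trace.append(opt.lr)
        order = rng.permutation(len(x))
        epoch_losses = []
        preds, targets = [], []
        for lo in range(0, len(x), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            loss, batch_pred = _batch_loss(model, x[idx], y[idx], weights, rng)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"loss diverged (non-finite) at epoch {epoch}, "
                    f"step {lo // cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            preds.append(batch_pred)
            targets.append(y[idx])
        loss_trace.append(float(np.mean(epoch_losses)))
        last_preds = np.concatenate(preds)
        last_targets = np.concatenate(targets)
    acc = float((last_preds == last_targets).mean()) if len(last_preds) else 0.0
    return TrainResult(loss_trace, lr_trace, acc)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion(y_true, y_pred, n_classes: int = 5) -> np.ndarray:
    """Confusion matrix: rows actual, columns predicted."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class EvalReport:
    """Scoring metrics computed from a confusion matrix (fractions)."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f: float                 # mean of per-class F1
    macro_f_harmonic: float        # 2·P·R/(P+R) on the macro averages
    kappa: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    empty_classes: list[str] = field(default_factory=list)

    def to_dict(self, percent: bool = True) -> dict:
        """JSON-ready dict; rates as percent (1 d.p.), kappa to 2 d.p."""
        scale, nd = (100.0, 1) if percent else (1.0, 4)
        r = lambda v: round(v * scale, nd)
        return {
            "accuracy": r(self.accuracy),
            "macro_precision": r(self.macro_precision),
            "macro_recall": r(self.macro_recall),
            "macro_f": r(self.macro_f),
            "macro_f_harmonic": r(self.macro_f_harmonic),
            "kappa": round(self.kappa, 2),
            "per_class": {
                s: {"precision": r(self.precision[s]),
                    "recall": r(self.recall[s]),
                    "f1": r(self.f1[s]),
                    "support": self.support[s]}
                for s in self.precision
            },
            "empty_classes": list(self.empty_classes),
        }


def evaluate(cm: np.ndarray,
             class_names: tuple[str, ...] = STAGES) -> EvalReport:
    """Metric suite from a confusion matrix.

    accuracy = trace/total; per-class precision TP/(TP+FP) and recall
    TP/(TP+FN); macro averages are unweighted class means; kappa uses
    p_e = Σ_i row_i·col_i / total².  Classes absent from both rows and
    columns score 0 and are flagged.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    cm = cm.astype(np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(cm)
    row = cm.sum(axis=1)   # actual totals (TP + FN)
    col = cm.sum(axis=0)   # predicted totals (TP + FP)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(col > 0, tp / col, 0.0)
        rec = np.where(row > 0, tp / row, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    empty = [class_names[i] for i in range(len(class_names))
             if row[i] == 0 and col[i] == 0]
    accuracy = float(tp.sum() / total)
    macro_p = float(prec.mean())
    macro_r = float(rec.mean())
    macro_f = float(f1.mean())
    macro_f_h = (2 * macro_p * macro_r / (macro_p + macro_r)
                 if macro_p + macro_r > 0 else 0.0)
    pe = float((row * col).sum() / total ** 2)
    kappa = (accuracy - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    names = list(class_names)
    return EvalReport(
        accuracy=accuracy,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f=macro_f,
        macro_f_harmonic=float(macro_f_h),
        kappa=float(kappa),
        precision=dict(zip(names, prec.tolist())),
        recall=dict(zip(names, rec.tolist())),
        f1=dict(zip(names, f1.tolist())),
        support=dict(zip(names, row.astype(int).tolist())),
        empty_classes=empty,
    )


# ---------------------------------------------------------------------------
# confusion-matrix TSV exchange
# ---------------------------------------------------------------------------

def write_confusion_tsv(path: str | Path, cm: np.ndarray,
                        class_names: tuple[str, ...] = STAGES) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("actual\\predicted\t" + "\t".join(class_names) + "\n")
        for name, rowvals in zip(class_names, np.asarray(cm)):
            fh.write(name + "\t" + "\t".join(str(int(v)) for v in rowvals)
                     + "\n")
    return path


def read_confusion_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a labeled 5×5 (or n×n) confusion TSV: header row + row labels."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = header[1:]
        rows, row_names = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            row_names.append(parts[0])
            rows.append([int(v.replace(",", "")) for v in parts[1:]])
    cm = np.array(rows, dtype=np.int64)
    if cm.shape[0] != cm.shape[1] or row_names != names:
        raise ValueError(f"{path}: malformed confusion matrix")
    return cm, names
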