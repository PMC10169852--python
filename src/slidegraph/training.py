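"""Label tasks, case-grouped cross-validation, training and evaluation.

Three classification tasks share one label schema:

* T1 (2 classes): healthy vs tumor of any grade;
* T2 (3 classes): healthy / low-risk (superficial, nodular) / high-risk
  (medium, high) — the WHO-style grouping;
* T3 (5 classes): healthy plus the four Sabbatsberg grades.

Slides inherit the worst subtype present (severity order healthy <
superficial < nodular < medium < high). Cross-validation folds are built at
the case (extraction) level so slides of one case never straddle folds; the
per-fold models are combined by majority vote, ties broken by the highest
mean probability among the tied classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

from .graph import SlideGraph
from .model import GraphTransformer, ModelConfig, Prediction, model_forward
from .nn import Adam, cross_entropy
from .synthetic import SUBTYPES

__all__ = [
    "TaskSpec",
    "TrainConfig",
    "FoldAssignment",
    "EvaluationReport",
    "map_label",
    "worst_subtype",
    "grouped_kfold",
    "train_model",
    "TrainResult",
    "ensemble_predict",
    "evaluate",
    "mean_roc",
]

_SEVERITY = {s: i for i, s in enumerate(SUBTYPES)}

_TASK_TABLE = {
    "T1": {"healthy": 0, "superficial": 1, "nodular": 1, "medium": 1, "high": 1},
    "T2": {"healthy": 0, "superficial": 1, "nodular": 1, "medium": 2, "high": 2},
    "T3": {"healthy": 0, "superficial": 1, "nodular": 2, "medium": 3, "high": 4},
}

_TASK_NAMES = {
    "T1": ("healthy", "tumor"),
    "T2": ("healthy", "low-risk", "high-risk"),
    "T3": ("healthy", "superficial", "nodular", "medium", "high"),
}


@dataclass(frozen=True)
class TaskSpec:
    task: str
    mapping: dict = field(hash=False)
    class_names: tuple

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @classmethod
    def for_task(cls, task: str) -> "TaskSpec":
        if task not in _TASK_TABLE:
            raise ValueError(f"unknown task {task!r}; expected T1, T2 or T3")
        return cls(task=task, mapping=dict(_TASK_TABLE[task]),
                   class_names=_TASK_NAMES[task])


def map_label(subtype: str, task: TaskSpec | str) -> int:
    """Class index of a subtype under a task's label mapping."""
    if isinstance(task, str):
        task = TaskSpec.for_task(task)
    if subtype not in task.mapping:
        raise ValueError(f"unknown subtype {subtype!r}")
    return task.mapping[subtype]


def worst_subtype(slide_subtypes) -> str:
    """Most aggressive subtype present (slides/cases inherit the worst grade)."""
    subtypes = list(slide_subtypes)
    if not subtypes:
        raise ValueError("worst_subtype of an empty list is undefined")
    for s in subtypes:
        if s not in _SEVERITY:
            raise ValueError(f"unknown subtype {s!r}")
    return max(subtypes, key=_SEVERITY.__getitem__)


@dataclass
class FoldAssignment:
    """case_id -> fold index; every case in exactly one fold."""

    fold_of: dict
    k: int

    def slide_folds(self, case_ids) -> np.ndarray:
        return np.array([self.fold_of[c] for c in case_ids], dtype=np.int64)

    def cases_in_fold(self, fold: int) -> list:
        return [c for c, f in self.fold_of.items() if f == fold]


def grouped_kfold(case_ids, k: int, seed: int = 0) -> FoldAssignment:
    """Partition cases (not slides) into k folds, sizes as even as possible.

    `case_ids` may contain repeats (one entry per slide); folds are formed
    over the unique cases, deterministically for a given seed.
    """
    unique = list(dict.fromkeys(case_ids))  # first-appearance order
    if len(unique) < k:
        raise ValueError(f"need at least {k} cases for {k} folds, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    fold_of = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            fold_of[unique[idx]] = fold
    return FoldAssignment(fold_of=fold_of, k=k)


@dataclass
class TrainConfig:
    batch_size: int = 4
    epochs: int = 100
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    lr_decay_steps: tuple = (40, 80)
    lr_decay_factor: float = 0.1
    k_folds: int = 5
    aux_loss_weight: float = 1.0
    class_weighting: bool = False   # off by default: no re-weighting despite imbalance
    seed: int = 0

    def __post_init__(self):
        for name in ("batch_size", "epochs", "learning_rate", "weight_decay",
                     "lr_decay_factor", "k_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(s >= self.epochs for s in self.lr_decay_steps):
            raise ValueError("lr decay steps must precede the final epoch")

    def lr_at_epoch(self, epoch: int) -> float:
        """Stepped schedule: base * factor^(number of passed decay steps)."""
        passed = sum(1 for s in self.lr_decay_steps if epoch >= s)
        return self.learning_rate * self.lr_decay_factor**passed


@dataclass
class TrainResult:
    model: GraphTransformer
    loss_trace: list            # mean total loss per epoch
    lr_trace: list              # learning rate per epoch


def train_model(graphs: list[SlideGraph], labels, model_cfg: ModelConfig,
                cfg: TrainConfig, seed: int | None = None) -> TrainResult:
    """Train one graph-transformer on (graph, class-index) pairs.

    Optimises cross entropy plus the min-cut auxiliary losses with Adam and
    the stepped learning-rate schedule; gradients are accumulated over
    `batch_size` graphs per step. Deterministic for a fixed seed.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if len(graphs) != len(labels):
        raise ValueError("graphs and labels must have equal length")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training fold contains a single class")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = GraphTransformer(model_cfg, rng=rng)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    weights = np.ones(model_cfg.n_classes)
    if cfg.class_weighting:
        for c, n in zip(classes, counts):
            weights[c] = len(labels) / (len(classes) * n)
    loss_trace, lr_trace = [], []
    n = len(graphs)
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at_epoch(epoch)
        lr_trace.append(opt.lr)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for i in idx:
                res = model.forward(graphs[i])
                loss = cross_entropy(res.logits, int(labels[i])) * weights[labels[i]] \
                    + cfg.aux_loss_weight * (res.cut_loss + res.ortho_loss)
                loss.backward(np.asarray(1.0 / len(idx)))
                batch_loss += loss.item() / len(idx)
            opt.step()
            epoch_losses.append(batch_loss)
        loss_trace.append(float(np.mean(epoch_losses)))
    return TrainResult(model=model, loss_trace=loss_trace, lr_trace=lr_trace)


def cross_validate(graphs: list[SlideGraph], labels, case_ids,
                   model_cfg: ModelConfig, cfg: TrainConfig,
                   seed: int | None = None) -> tuple[list[TrainResult], FoldAssignment]:
    """Train one model per fold on the k-1 training folds (grouped by case)."""
    seed = cfg.seed if seed is None else seed
    assignment = grouped_kfold(case_ids, cfg.k_folds, seed=seed)
    folds = assignment.slide_folds(case_ids)
    results = []
    for fold in range(cfg.k_folds):
        keep = folds != fold
        res = train_model([g for g, k_ in zip(graphs, keep) if k_],
                          np.asarray(labels)[keep], model_cfg, cfg,
                          seed=seed + fold + 1)
        results.append(res)
    return results, assignment


def ensemble_predict(per_model_predictions: list[Prediction]) -> int:
    """Majority vote over the fold models' predicted classes.

    Ties are broken by the highest mean probability among the tied classes.
    """
    if not per_model_predictions:
        raise ValueError("ensemble_predict needs at least one prediction")
    votes = np.array([p.predicted_class for p in per_model_predictions])
    probs = np.stack([p.probabilities for p in per_model_predictions])
    counts = np.bincount(votes, minlength=probs.shape[1])
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if len(tied) == 1:
        return int(tied[0])
    mean_probs = probs.mean(axis=0)
    return int(tied[np.argmax(mean_probs[tied])])


@dataclass
class EvaluationReport:
    task: str
    accuracy: float                       # fraction in [0, 1]
    sensitivity: list                     # per class, None when class absent
    specificity: list
    auc: list                             # one-vs-rest, None when undefined
    confusion: np.ndarray                 # (n_classes, n_classes), rows = truth
    n: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "task": self.task,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate(predictions: list[Prediction] | np.ndarray, truths,
             task: TaskSpec | str) -> EvaluationReport:
    """Accuracy, per-class sensitivity/specificity (one-vs-rest), AUC, confusion.

    `predictions` is either a list of Prediction objects (AUC uses their
    probabilities) or a plain array of predicted class indices (AUC omitted).
    A class absent from the truths has undefined sensitivity, reported as None.
    """
    if isinstance(task, str):
        task = TaskSpec.for_task(task)
    truths = np.asarray(truths, dtype=np.int64)
    if isinstance(predictions, (list, tuple)) and predictions and \
            isinstance(predictions[0], Prediction):
        preds = np.array([p.predicted_class for p in predictions])
        probs = np.stack([p.probabilities for p in predictions])
    else:
        preds = np.asarray(predictions, dtype=np.int64)
        probs = None
    if len(preds) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    ncls = task.n_classes
    cm = _sk_confusion(truths, preds, labels=np.arange(ncls))
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total
    sensitivity, specificity, auc = [], [], []
    for c in range(ncls):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sensitivity.append(float(tp / (tp + fn)) if (tp + fn) > 0 else None)
        specificity.append(float(tn / (tn + fp)) if (tn + fp) > 0 else None)
        if probs is not None and 0 < (truths == c).sum() < len(truths):
            auc.append(float(roc_auc_score((truths == c).astype(int), probs[:, c])))
        else:
            auc.append(None)
    return EvaluationReport(task=task.task, accuracy=accuracy,
                            sensitivity=sensitivity, specificity=specificity,
                            auc=auc, confusion=cm, n=int(total))


def mean_roc(fold_truths: list, fold_probs: list, target_class: int,
             grid_size: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Mean one-vs-rest ROC across folds by vertical averaging.

    Interpolates each fold's ROC onto a fixed false-positive-rate grid and
    averages the true-positive rates, as is standard for mean CV ROC curves.
    """
    fpr_grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for truths, probs in zip(fold_truths, fold_probs):
        y = (np.asarray(truths) == target_class).astype(int)
        if y.min() == y.max():
            continue
        fpr, tpr, _ = roc_curve(y, np.asarray(probs)[:, target_class])
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    if not tprs:
        raise ValueError("no fold had both classes present")
    return fpr_grid, np.mean(tprs, axis=0)
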