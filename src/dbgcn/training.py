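"""Subject-wise cross-validation, Adam training, and confusion-matrix metrics.

Fold construction is at the subject level: all of a subject's segments travel
together, so no individual ever contributes data to both the training and the
validation side of a fold.  Within each fold's training subjects an inner
90/10 subject split monitors generalization across epochs and selects the
best checkpoint; the held-out fold is touched only once, for the final
evaluation.  The correlation graph and the feature normalizer are likewise
fitted on the fold's training subjects only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import model as M
from .features import (DEFAULT_BANDS, BandSpec, FeatureTensor, apply_normalizer,
                       build_feature_tensor, fit_normalizer)
from .graph import BrainGraph, adjacency_from_data
from .preprocess import FilterSpec, apply_filters, baseline_correct, segment
from .recording import RawRecording

__all__ = [
    "TrainConfig",
    "PipelineConfig",
    "FoldMetrics",
    "ArrayDataset",
    "subjectwise_kfold",
    "train",
    "evaluate",
    "cross_validate",
    "metrics_from_counts",
]

logger = logging.getLogger("dbgcn.training")


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The defaults (Adam, 100 epochs, batch 512, learning rate 1e-5, dropout
    handled by the model config) target full-size datasets with thousands of
    segments; scaled-down experiments should raise the learning rate and
    shrink epochs/batch accordingly.
    """

    optimizer: str = "adam"
    epochs: int = 100
    batch_size: int = 512
    learning_rate: float = 1e-5
    k_folds: int = 10
    inner_train_fraction: float = 0.9
    class_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.inner_train_fraction < 1:
            raise ValueError("inner_train_fraction must be in (0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class PipelineConfig:
    """End-to-end preprocessing and feature options used inside cross-validation."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    baseline_s: float | None = 120.0
    window_s: float = 4.0
    stride_s: float = 2.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    t_subwindows: int = 4
    feature_kind: str = "DE"
    signed_policy: str = "abs"


@dataclass
class FoldMetrics:
    """Confusion-matrix counts and the derived rates for one validation fold.

    The depressed class (label 1) is the positive class.  Rates whose
    denominator is zero (e.g. precision under a never-positive predictor) are
    reported as 0.0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        total = self.tp + self.fp + self.tn + self.fn
        if total == 0:
            raise ValueError("empty confusion matrix")
        self.accuracy = (self.tp + self.tn) / total
        self.precision = _safe_div(self.tp, self.tp + self.fp)
        self.sensitivity = _safe_div(self.tp, self.tp + self.fn)
        self.specificity = _safe_div(self.tn, self.tn + self.fp)
        self.f1 = _safe_div(2 * self.precision * self.sensitivity,
                            self.precision + self.sensitivity)

    @property
    def n_samples(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def confusion_matrix(self) -> np.ndarray:
        """2x2 matrix, rows = true label (0, 1), columns = predicted label."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=np.int64)

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "f1": self.f1,
        }


def _safe_div(num: float, den: float) -> float:
    return float(num / den) if den else 0.0


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> FoldMetrics:
    return FoldMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class ArrayDataset:
    """Segments ready for the network: features, labels, and segment->subject map."""

    X: np.ndarray            # (N, n_channels, t, d)
    y: np.ndarray            # (N,) int labels
    subjects: np.ndarray     # (N,) subject id per segment

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, subject_ids) -> "ArrayDataset":
        mask = np.isin(self.subjects, list(subject_ids))
        return ArrayDataset(self.X[mask], self.y[mask], self.subjects[mask])


def subjectwise_kfold(subject_ids, k: int = 10, seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Partition subjects (not segments) into k near-equal validation groups.

    Subjects are shuffled by the seed and split; each subject appears in
    exactly one validation group, so every one of their segments stays on one
    side of each fold.
    """
    unique: list[str] = []
    for s in subject_ids:
        if s not in unique:
            unique.append(s)
    if len(unique) < k:
        raise ValueError(f"{len(unique)} subjects cannot form {k} folds")
    order = np.random.default_rng(seed).permutation(len(unique))
    shuffled = [unique[i] for i in order]
    groups = np.array_split(np.arange(len(shuffled)), k)
    folds = []
    for grp in groups:
        val = [shuffled[i] for i in grp]
        trainset = [s for s in shuffled if s not in val]
        folds.append((trainset, val))
    return folds


class _Adam:
    """Adam with bias correction; one slot pair per parameter array."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k in params:
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grads[k]
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grads[k] ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class _SGD:
    def __init__(self, params, lr):
        self.lr = lr

    def step(self, params, grads):
        for k in params:
            params[k] -= self.lr * grads[k]


def train(
    model_cfg: M.ModelConfig,
    train_cfg: TrainConfig,
    dataset: ArrayDataset,
    stack: M.GraphStack,
    inner_val: ArrayDataset | None = None,
    init_seed: int | None = None,
):
    """Minibatch training of the full network.

    Runs ``epochs`` passes of shuffled minibatches, recording per-epoch mean
    training loss and (if ``inner_val`` is given) inner-validation accuracy;
    the returned parameters are the checkpoint with the best inner accuracy,
    or the final parameters when no inner set is provided.
    Returns ``(params, history)``.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    init_seed = train_cfg.seed if init_seed is None else init_seed
    params = M.init_params(model_cfg, seed=init_seed)
    batch = min(train_cfg.batch_size, len(dataset))
    if batch < train_cfg.batch_size:
        logger.warning("batch_size %d clamped to dataset size %d", train_cfg.batch_size, batch)
    opt = (_Adam if train_cfg.optimizer == "adam" else _SGD)(params, train_cfg.learning_rate)
    class_weight = None
    if train_cfg.class_weights:
        counts = np.bincount(dataset.y, minlength=model_cfg.n_classes)
        if np.all(counts > 0):
            # inverse-frequency weights counter the mechanical class imbalance
            # that subject-wise folds induce in small cohorts
            class_weight = len(dataset) / (model_cfg.n_classes * counts)
    rng_shuffle = np.random.default_rng([init_seed % (2 ** 31), 1])
    rng_dropout = np.random.default_rng([init_seed % (2 ** 31), 2])
    history = {"train_loss": [], "inner_accuracy": []}
    best = {"acc": -1.0, "params": {k: v.copy() for k, v in params.items()}}
    n_batches = math.ceil(len(dataset) / batch)
    for epoch in range(train_cfg.epochs):
        perm = rng_shuffle.permutation(len(dataset))
        epoch_loss = 0.0
        for bi in range(n_batches):
            idx = perm[bi * batch:(bi + 1) * batch]
            loss_val, grads = M.loss_and_grads(
                dataset.X[idx], dataset.y[idx], stack, params, model_cfg,
                rng=rng_dropout, class_weight=class_weight,
            )
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {bi}: {loss_val}"
                )
            opt.step(params, grads)
            epoch_loss += loss_val * len(idx)
        history["train_loss"].append(epoch_loss / len(dataset))
        if inner_val is not None and len(inner_val) > 0:
            acc = evaluate(params, inner_val, stack, model_cfg).accuracy
            history["inner_accuracy"].append(acc)
            # ties go to the later epoch: with a small inner set many epochs
            # share the top accuracy and the most-trained one generalizes best
            if acc >= best["acc"]:
                best = {"acc": acc, "params": {k: v.copy() for k, v in params.items()}}
    final = best["params"] if inner_val is not None and len(inner_val) > 0 else params
    return final, history


def evaluate(params, dataset: ArrayDataset, stack: M.GraphStack, model_cfg: M.ModelConfig) -> FoldMetrics:
    """Argmax predictions over a dataset, reduced to confusion-matrix metrics."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    preds = np.empty(len(dataset), dtype=np.int64)
    chunk = 1024
    for start in range(0, len(dataset), chunk):
        probs = M.forward(dataset.X[start:start + chunk], stack, params, model_cfg, train=False)
        preds[start:start + chunk] = probs.argmax(axis=1)
    y = dataset.y
    tp = int(np.sum((preds == 1) & (y == 1)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    return FoldMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def preprocess_and_featurize(recordings: list[RawRecording], pipe: PipelineConfig):
    """Filter, baseline-correct, window, and featurize every recording.

    Returns ``(clean, tensors)``: the preprocessed continuous recordings
    (used later for training-fold adjacency estimation) and the unnormalized
    per-segment feature tensors.
    """
    clean: list[RawRecording] = []
    tensors: list[FeatureTensor] = []
    for rec in recordings:
        out = apply_filters(rec, pipe.filter_spec)
        if pipe.baseline_s is not None:
            out = baseline_correct(out, baseline_s=min(pipe.baseline_s, out.duration_s))
        segments = segment(out, window_s=pipe.window_s, stride_s=pipe.stride_s)
        logger.info("subject %s: %d channels, %d segments", rec.subject_id,
                    out.n_channels, len(segments))
        clean.append(out)
        for seg in segments:
            tensors.append(build_feature_tensor(seg, bands=pipe.bands,
                                                t_subwindows=pipe.t_subwindows,
                                                feature_kind=pipe.feature_kind))
    return clean, tensors


def _dataset_from_tensors(tensors: list[FeatureTensor], stats) -> ArrayDataset:
    normed = [apply_normalizer(t, stats) for t in tensors]
    X = np.stack([t.values for t in normed])
    y = np.array([t.label for t in normed], dtype=np.int64)
    subjects = np.array([t.subject_id for t in normed])
    return ArrayDataset(X, y, subjects)


def training_fold_graph(clean: list[RawRecording], train_subjects, signed_policy: str = "abs") -> BrainGraph:
    """Correlation adjacency from the concatenated recordings of the training subjects."""
    keep = [r for r in clean if r.subject_id in set(train_subjects)]
    if not keep:
        raise ValueError("no training-subject recordings found")
    data = np.concatenate([r.data for r in keep], axis=1)
    return adjacency_from_data(data, keep[0].channel_names)


@dataclass
class CVResult:
    fold_metrics: list[FoldMetrics]
    summary: dict[str, tuple[float, float]]
    histories: list[dict]

    def mean(self, metric: str) -> float:
        return self.summary[metric][0]


def cross_validate(
    recordings: list[RawRecording],
    model_cfg: M.ModelConfig,
    train_cfg: TrainConfig,
    pipe: PipelineConfig | None = None,
) -> CVResult:
    """Subject-wise k-fold cross-validation of the full pipeline.

    Per fold: the correlation graph, its pooling hierarchy, and the feature
    normalizer are fitted on the training subjects only; an inner 90/10
    subject split of the training side selects the best epoch; the held-out
    subjects are evaluated exactly once.  The summary maps each metric to its
    (mean, sample standard deviation) across folds.
    """
    pipe = pipe or PipelineConfig()
    clean, tensors = preprocess_and_featurize(recordings, pipe)
    subject_order = [r.subject_id for r in recordings]
    folds = subjectwise_kfold(subject_order, k=train_cfg.k_folds, seed=train_cfg.seed)

    fold_metrics: list[FoldMetrics] = []
    histories: list[dict] = []
    for fold_idx, (train_subjects, val_subjects) in enumerate(folds):
        fold_seed = (train_cfg.seed * 1009 + fold_idx) % (2 ** 31)
        # inner subject split of the training side, for epoch selection
        rng = np.random.default_rng([train_cfg.seed % (2 ** 31), 7, fold_idx])
        shuffled = list(np.array(train_subjects)[rng.permutation(len(train_subjects))])
        n_inner_train = max(1, min(len(shuffled) - 1,
                                   int(round(train_cfg.inner_train_fraction * len(shuffled)))))
        inner_train_subjects = shuffled[:n_inner_train]
        inner_val_subjects = shuffled[n_inner_train:]

        graph = training_fold_graph(clean, train_subjects, pipe.signed_policy)
        stack = M.build_graph_stack(graph, model_cfg.n_gcn_layers, signed_policy=pipe.signed_policy)
        train_tensors = [t for t in tensors if t.subject_id in set(train_subjects)]
        stats = fit_normalizer(train_tensors)
        full = _dataset_from_tensors(tensors, stats)

        inner_train = full.subset(inner_train_subjects)
        inner_val = full.subset(inner_val_subjects)
        held_out = full.subset(val_subjects)

        params, history = train(model_cfg, train_cfg, inner_train, stack,
                                inner_val=inner_val, init_seed=fold_seed)
        metrics = evaluate(params, held_out, stack, model_cfg)
        logger.info("fold %d: accuracy %.3f on %d held-out segments",
                    fold_idx, metrics.accuracy, metrics.n_samples)
        fold_metrics.append(metrics)
        histories.append(history)

    summary = {}
    for name in ("accuracy", "precision", "sensitivity", "specificity", "f1"):
        vals = np.array([getattr(m, name) for m in fold_metrics])
        summary[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return CVResult(fold_metrics=fold_metrics, summary=summary, histories=histories)
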