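"""Supervised spiking readout (rank-order + drift) and LOOCV evaluation.

One output neuron is created per training sample.  Its weight to reservoir
neuron n is initialized ``mod ** rank`` where rank is n's position in the
order of first spikes within the sample's raster (silent neurons get 0), and
is then adjusted by +drift for every later spike of n and -drift for every
later silent step — the dynamic-synapse variant used by evolving-SNN
readouts.  Prediction compares the test sample's vector to the stored output
neurons by Euclidean distance (k nearest, majority label).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ReadoutParams:
    mod: float = 0.9
    drift: float = 0.25
    k: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.mod < 1:
            raise ValueError("mod must be in (0, 1)")
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1")


@dataclass
class ReadoutModel:
    vectors: np.ndarray  # (n_samples, n_neurons)
    labels: list[str]
    params: ReadoutParams

    @property
    def n_outputs(self) -> int:
        return self.vectors.shape[0]


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome.

    ``confusion`` has actual classes as rows, predicted as columns, in
    ``classes`` order; accuracies are percentages rounded to 2 decimals.
    """

    classes: tuple[str, ...]
    per_fold: list[tuple[str, str, str]]  # (sample id, true, predicted)
    confusion: np.ndarray
    class_accuracy: dict[str, float]
    total_accuracy: float
    meta: dict = field(default_factory=dict)

    def folds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold, columns=["sample", "actual", "predicted"])


def rank_order_vector(raster: np.ndarray, params: ReadoutParams) -> np.ndarray:
    """Output-neuron weight vector for one reservoir raster (neurons x time)."""
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ValueError("raster must be neurons x time")
    n, t_steps = raster.shape
    spiked = raster.any(axis=1)
    first = np.where(spiked, raster.argmax(axis=1), t_steps)
    w = np.zeros(n)
    idx = np.flatnonzero(spiked)
    if idx.size:
        # rank by first-spike time, ties by neuron index (stable sort)
        order = idx[np.argsort(first[idx], kind="stable")]
        w[order] = params.mod ** np.arange(order.size)
        counts = raster[idx].sum(axis=1)
        later = t_steps - 1 - first[idx]  # steps after the first spike
        extra_spikes = counts - 1
        w[idx] += params.drift * (extra_spikes - (later - extra_spikes))
    return w


def fit_readout(
    rasters: list[np.ndarray], labels: list[str], params: ReadoutParams = ReadoutParams()
) -> ReadoutModel:
    """Create one output neuron per training sample."""
    if len(rasters) != len(labels) or not rasters:
        raise ValueError("rasters and labels must be equal-length and non-empty")
    if len(set(labels)) < 2:
        raise ValueError("training set must contain at least two classes")
    vectors = np.stack([rank_order_vector(r, params) for r in rasters])
    return ReadoutModel(vectors=vectors, labels=list(labels), params=params)


def _knn_predict(
    vectors: np.ndarray, labels: list[str], x: np.ndarray, k: int
) -> str:
    d = np.sqrt(((vectors - x) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")
    k = min(k, len(labels))
    top = [labels[i] for i in order[:k]]
    counts: dict[str, int] = {}
    for lab in top:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    if len(winners) == 1:
        return winners[0]
    # tie: class of the single nearest neighbour among the tied classes
    for i in order:
        if labels[i] in winners:
            return labels[i]
    raise RuntimeError("unreachable")


def predict(model: ReadoutModel, raster: np.ndarray) -> str:
    """Classify one raster by its k nearest output neurons."""
    if model.n_outputs == 0:
        raise ValueError("readout model is not fitted")
    x = rank_order_vector(raster, model.params)
    return _knn_predict(model.vectors, model.labels, x, model.params.k)


def confusion_metrics(confusion: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class and total accuracy (percent, rounded to 2 decimals).

    ``confusion`` rows are actual classes, columns predicted.  A class with
    no actual samples has undefined accuracy and raises.
    """
    c = np.asarray(confusion)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
        raise ValueError("confusion entries must be non-negative numbers")
    row_sums = c.sum(axis=1)
    if c.sum() <= 0:
        raise ValueError("confusion matrix is empty")
    if np.any(row_sums == 0):
        empty = int(np.flatnonzero(row_sums == 0)[0])
        raise ValueError(f"class {empty} has no actual samples; accuracy undefined")
    class_acc = np.round(100.0 * np.diag(c) / row_sums, 2)
    total = round(100.0 * np.trace(c) / c.sum(), 2)
    return class_acc, float(total)


def loocv(
    rasters: list[np.ndarray],
    labels: list[str],
    params: ReadoutParams = ReadoutParams(),
    sample_ids: list[str] | None = None,
    groups: list[str] | None = None,
    classes: tuple[str, ...] | None = None,
) -> CVResult:
    """Leave-one-out cross-validation over samples (deterministic fold order).

    With ``groups`` given (e.g. subject ids), folds leave out one group at a
    time instead of one sample, avoiding within-subject leakage.  Output
    vectors depend only on their own raster, so each fold's readout is the
    remaining samples' vectors.
    """
    n = len(rasters)
    if n < 2 or len(labels) != n:
        raise ValueError("need >= 2 samples with matching labels")
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if classes is None:
        classes = tuple(dict.fromkeys(labels))
    vectors = np.stack([rank_order_vector(r, params) for r in rasters])
    if groups is None:
        holdouts = [[i] for i in range(n)]
    else:
        if len(groups) != n:
            raise ValueError("groups must match samples")
        holdouts = [
            [i for i in range(n) if groups[i] == g] for g in dict.fromkeys(groups)
        ]
    per_fold: list[tuple[str, str, str]] = []
    for held in holdouts:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        train_labels = [labels[i] for i in np.flatnonzero(mask)]
        if len(set(train_labels)) < 2:
            raise ValueError("a fold's training set is single-class")
        train_vecs = vectors[mask]
        for i in held:
            pred = _knn_predict(train_vecs, train_labels, vectors[i], params.k)
            per_fold.append((sample_ids[i], labels[i], pred))
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for _, true, pred in per_fold:
        confusion[cls_index[true], cls_index[pred]] += 1
    class_acc, total = confusion_metrics(confusion)
    return CVResult(
        classes=classes,
        per_fold=per_fold,
        confusion=confusion,
        class_accuracy={c: float(class_acc[i]) for i, c in enumerate(classes)},
        total_accuracy=total,
        meta={"n_folds": len(per_fold), "unit": "sample" if groups is None else "group"},
    )
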