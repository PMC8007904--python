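"""Imbalance handling, data partitioning, metrics, and cross-correlograms.

Positive intervals (target spikes) are rare next to the negatives that tile
the rest of the recording, so models are trained on an undersampled "snap"
set: all positives plus ``ratio`` times as many randomly drawn negatives
(default 1:4).  The snap set splits 80/20 into training and validation,
stratified by class.  A fitted model is then scored on four nested subsets
— training, validation, snap, and the complete table — with precision,
recall, and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

computed from the confusion matrix with rows = predicted, columns = actual.
Complete-set MCC is the headline number: the snap subsets describe the
training regime, while the complete set is the realistic class balance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .c5tree import CostMatrix, FitConfig, TreeModel, fit_tree, predict, primary_group
from .c5tree import EncodedTable
from .intervals import IntervalTable
from .netsim import SpikeTrainSet

__all__ = [
    "ConfusionMatrix",
    "MetricsResult",
    "SnapPartition",
    "RunResult",
    "MultiSeedResult",
    "snap_sample",
    "confusion",
    "compute_metrics",
    "run_once",
    "run_multi_seed",
    "spawn_seeds",
    "crosscorrelogram",
    "SUBSETS",
]

SUBSETS = ("complete", "snap", "training", "validation")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsResult:
    precision: float
    recall: float
    mcc: float


@dataclass
class SnapPartition:
    """Snap = all positives + sampled negatives; 80/20 stratified split.

    All fields are integer row indices into the originating interval table.
    """

    snap: np.ndarray
    training: np.ndarray
    validation: np.ndarray
    seed: int
    ratio: float

    def __post_init__(self) -> None:
        tv = np.sort(np.concatenate([self.training, self.validation]))
        if not np.array_equal(tv, np.sort(self.snap)):
            raise ValueError("training and validation must partition the snap set")


@dataclass
class RunResult:
    """One fit: model, per-subset metrics, primary group, snap seed."""

    model: TreeModel
    metrics: dict[str, MetricsResult]
    primary_group: set[str]
    partition: SnapPartition
    seed: int


@dataclass
class MultiSeedResult:
    runs: list[RunResult]
    mean: dict[str, MetricsResult]
    sem: dict[str, MetricsResult]


def snap_sample(
    table: IntervalTable, ratio: float = 4.0, rng_seed: int = 0, train_frac: float = 0.8
) -> SnapPartition:
    """Undersample negatives and split snap 80/20 stratified by class.

    Keeps every positive row and ``ratio * positives`` negatives sampled
    uniformly without replacement (all of them, with a warning, when fewer
    are available).  Within each class, ``floor(train_frac * n)`` rows go to
    training and the remainder to validation.
    """
    y = table.y
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    if pos.size == 0:
        raise ValueError("snap sampling needs at least one positive interval")
    rng = np.random.default_rng(rng_seed)
    n_neg = int(round(ratio * pos.size))
    if neg.size < n_neg:
        warnings.warn(
            f"only {neg.size} negatives available for a 1:{ratio:g} snap of "
            f"{pos.size} positives; keeping all of them"
        )
        neg_sample = neg.copy()
        rng.shuffle(neg_sample)
    else:
        neg_sample = rng.choice(neg, size=n_neg, replace=False)

    def split(cls_rows: np.ndarray):
        perm = rng.permutation(cls_rows)
        k = int(math.floor(train_frac * perm.size))
        return perm[:k], perm[k:]

    pos_tr, pos_va = split(pos)
    neg_tr, neg_va = split(neg_sample)
    return SnapPartition(
        snap=np.sort(np.concatenate([pos, neg_sample])),
        training=np.sort(np.concatenate([pos_tr, neg_tr])),
        validation=np.sort(np.concatenate([pos_va, neg_va])),
        seed=int(rng_seed),
        ratio=float(ratio),
    )


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(np.int8)
    y_pred = np.asarray(y_pred).astype(np.int8)
    return ConfusionMatrix(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        tn=int(np.sum((y_pred == 0) & (y_true == 0))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricsResult:
    """Precision, recall and MCC from a confusion matrix.

    A zero denominator (any empty margin) yields 0 for the affected metric.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = float(cm.tp), float(cm.tn), float(cm.fp), float(cm.fn)
    precision = tp / (fp + tp) if (fp + tp) > 0 else 0.0
    recall = tp / (fn + tp) if (fn + tp) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricsResult(precision=precision, recall=recall, mcc=mcc)


def run_once(
    table: IntervalTable | EncodedTable,
    units: list[str] | None = None,
    costs: CostMatrix | None = None,
    cfg: FitConfig | None = None,
    rng_seed: int = 0,
    ratio: float = 4.0,
    partition: SnapPartition | None = None,
) -> RunResult:
    """Snap-sample, fit on the training rows, score on all four subsets.

    ``table`` may be a pre-built :class:`EncodedTable`.  A pre-computed
    ``partition`` can be shared between calls so different unit subsets see
    identical training data.
    """
    costs = costs or CostMatrix()
    cfg = cfg or FitConfig(rng_seed=rng_seed)
    if isinstance(table, EncodedTable):
        enc = table
    else:
        enc = EncodedTable(table, None)
    y_all = enc.y
    if partition is None:
        partition = _snap_from_y(y_all, ratio, rng_seed)
    model = fit_tree(enc, costs, cfg, attributes=units, rows=partition.training)
    attr_cols = enc.column_subset(model.attributes)
    pred_all = predict(model, enc.X, attr_cols=attr_cols)
    subsets = {
        "complete": np.arange(enc.n),
        "snap": partition.snap,
        "training": partition.training,
        "validation": partition.validation,
    }
    metrics = {
        name: compute_metrics(confusion(y_all[idx], pred_all[idx]))
        for name, idx in subsets.items()
    }
    return RunResult(
        model=model,
        metrics=metrics,
        primary_group=primary_group(model),
        partition=partition,
        seed=int(rng_seed),
    )


def _snap_from_y(y: np.ndarray, ratio: float, rng_seed: int) -> SnapPartition:
    """snap_sample working directly on a class vector (EncodedTable path)."""
    shim = _YView(y)
    return snap_sample(shim, ratio=ratio, rng_seed=rng_seed)  # type: ignore[arg-type]


class _YView:
    """Minimal stand-in exposing just the class vector to snap_sample."""

    def __init__(self, y: np.ndarray):
        self._y = y

    @property
    def y(self) -> np.ndarray:
        return self._y


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Reproducible per-repetition seeds derived from one master seed."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_multi_seed(
    table: IntervalTable | EncodedTable,
    units: list[str] | None = None,
    costs: CostMatrix | None = None,
    cfg: FitConfig | None = None,
    n_seeds: int = 30,
    master_seed: int = 0,
    ratio: float = 4.0,
) -> MultiSeedResult:
    """Repeat :func:`run_once` with ``n_seeds`` different snap seeds.

    Reports per-subset mean and standard error of the mean (sample standard
    deviation over seeds divided by sqrt(n)).
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    enc = table if isinstance(table, EncodedTable) else EncodedTable(table, None)
    runs = [
        run_once(enc, units=units, costs=costs, cfg=cfg, rng_seed=s, ratio=ratio)
        for s in spawn_seeds(master_seed, n_seeds)
    ]
    mean: dict[str, MetricsResult] = {}
    sem: dict[str, MetricsResult] = {}
    for name in SUBSETS:
        vals = {
            m: np.array([getattr(r.metrics[name], m) for r in runs])
            for m in ("precision", "recall", "mcc")
        }
        mean[name] = MetricsResult(**{m: float(v.mean()) for m, v in vals.items()})
        sem[name] = MetricsResult(
            **{m: float(v.std(ddof=1) / math.sqrt(n_seeds)) for m, v in vals.items()}
        )
    return MultiSeedResult(runs=runs, mean=mean, sem=sem)


def crosscorrelogram(
    trigger: np.ndarray,
    other: np.ndarray,
    bin_ms: float = 1.0,
    window_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Lag histogram of ``other`` spikes around each ``trigger`` spike.

    Returns ``(lag_centers_ms, counts)`` for lags in ``[-window, +window]``
    ms; positive lags mean the other unit fired *after* the trigger.  Empty
    trains yield an all-zero histogram with a warning.
    """
    trigger = np.asarray(trigger, dtype=float)
    other = np.asarray(other, dtype=float)
    window_s = window_ms / 1000.0
    bin_s = bin_ms / 1000.0
    n_bins = 2 * int(round(window_ms / bin_ms))
    edges = np.linspace(-window_s, window_s, n_bins + 1)
    centers = 1000.0 * (edges[:-1] + edges[1:]) / 2.0
    counts = np.zeros(n_bins, dtype=np.int64)
    if trigger.size == 0 or other.size == 0:
        warnings.warn("empty spike train; cross-correlogram is all zeros")
        return centers, counts
    lo = np.searchsorted(other, trigger - window_s, side="left")
    hi = np.searchsorted(other, trigger + window_s, side="right")
    for t, a, b in zip(trigger, lo, hi):
        lags = other[a:b] - t
        counts += np.histogram(lags, bins=edges)[0]
    return centers, counts
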