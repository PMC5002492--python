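"""Yield-class discretization and weighted knn diagnosis in ilr space.

Specimens are split into high and low yielders at a cutoff chosen by the
analyst.  Because a specimen is flagged ("positive") when misbalance is
suspected, the *low* yielder is the positive class and the high yielder the
negative class.  A weighted k-nearest-neighbour classifier — Minkowski
distance on ilr coordinates, distance-kernel neighbour weights, the setup of
the kknn family of classifiers — predicts the class; crossing predictions
with observed classes partitions the specimens into

* TN: predicted high, observed high — balanced, high-yielding (the norm group)
* TP: predicted low, observed low — misbalanced (deficiency or excess)
* FN: predicted high, observed low — balanced but limited by other factors
* FP: predicted low, observed high — luxury consumption or contamination

from which accuracy, predictive values, sensitivity and specificity follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "HIGH",
    "LOW",
    "KnnConfig",
    "ConfusionPartition",
    "discretize_yield",
    "knn_predict",
    "tune_knn",
    "partition_confusion",
    "diagnostic_metrics",
]

HIGH = "high"  # negative class: no misbalance suspected
LOW = "low"    # positive class: misbalance suspected

KERNELS = ("rectangular", "triangular", "optimal")


@dataclass(frozen=True)
class KnnConfig:
    """Weighted knn hyperparameters.

    ``minkowski_p`` is the distance exponent in ilr space (2 = Euclidean);
    ``kernel`` weights neighbours by distance rank or scaled distance:
    rectangular = equal votes, triangular = 1 − d/d_(k+1), optimal =
    Samworth-type rank weights.  ``seed`` fixes vote tie-breaking.
    """

    k: int = 10
    minkowski_p: float = 4.0
    kernel: str = "optimal"
    folds: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.minkowski_p < 1:
            raise ValueError("Minkowski exponent must be ≥ 1")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; use one of {KERNELS}")
        if self.folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")


def discretize_yield(yields, cutoff: float) -> np.ndarray:
    """Classify yields as ``high`` (≥ cutoff, ties included) or ``low``."""
    if cutoff <= 0:
        raise ValueError("yield cutoff must be positive")
    y = np.asarray(yields, dtype=float)
    if (y < 0).any():
        raise ValueError("negative yields are not valid")
    return np.where(y >= cutoff, HIGH, LOW)


def _samworth_weights(k: int, dim: int) -> np.ndarray:
    """Samworth-type optimal rank weights for k neighbours in ``dim`` dims."""
    i = np.arange(1, k + 1, dtype=float)
    d = float(dim)
    w = (1.0 / k) * (
        1.0 + d / 2.0
        - d / (2.0 * k ** (2.0 / d)) * (i ** (1.0 + 2.0 / d) - (i - 1.0) ** (1.0 + 2.0 / d))
    )
    return np.clip(w, 0.0, None)


def _kernel_weights(dist: np.ndarray, k: int, kernel: str, dim: int) -> np.ndarray:
    """Weights for the first ``k`` neighbours, one row per query.

    ``dist`` holds k (or k+1, when the training set allows) sorted neighbour
    distances; the (k+1)-th distance is the triangular kernel's bandwidth.
    """
    n_query = dist.shape[0]
    if kernel == "rectangular":
        return np.ones((n_query, k))
    if kernel == "triangular":
        bw = dist[:, -1:]  # d_(k+1) when available, else the k-th distance
        w = 1.0 - dist[:, :k] / np.where(bw > 0, bw, 1.0)
        return np.clip(w, 0.0, None)
    if kernel == "optimal":
        return np.tile(_samworth_weights(k, dim), (n_query, 1))
    raise ValueError(f"unknown kernel {kernel!r}")


def knn_predict(
    train_coords,
    train_classes,
    query_coords,
    cfg: KnnConfig | None = None,
) -> np.ndarray:
    """Predict classes for query balance vectors by weighted knn vote.

    Deterministic: exact neighbour search, and vote ties broken by a class
    order shuffled once from ``cfg.seed``.
    """
    cfg = cfg or KnnConfig()
    X = np.asarray(train_coords, dtype=float)
    y = np.asarray(train_classes)
    Q = np.atleast_2d(np.asarray(query_coords, dtype=float))
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training set must be a nonempty coordinate matrix")
    if Q.shape[1] != X.shape[1]:
        raise ValueError("query and training coordinate dimensions differ")
    if y.shape[0] != X.shape[0]:
        raise ValueError("one class label per training specimen required")
    if cfg.k > X.shape[0]:
        raise ValueError(f"k={cfg.k} exceeds the training size {X.shape[0]}")

    n_neighbors = min(cfg.k + 1, X.shape[0])  # +1 supplies the kernel bandwidth
    nn = NearestNeighbors(n_neighbors=n_neighbors, metric="minkowski",
                          p=cfg.minkowski_p)
    nn.fit(X)
    dist, idx = nn.kneighbors(Q)
    k = min(cfg.k, X.shape[0])
    weights = _kernel_weights(dist, k, cfg.kernel, X.shape[1])
    neighbor_classes = y[idx[:, :k]]

    classes = np.unique(y)
    rng = np.random.default_rng(cfg.seed)
    tie_order = classes[rng.permutation(len(classes))]
    scores = np.stack(
        [np.where(neighbor_classes == c, weights, 0.0).sum(axis=1) for c in classes],
        axis=1,
    )
    best = scores.max(axis=1, keepdims=True)
    predictions = np.empty(Q.shape[0], dtype=y.dtype)
    for row in range(Q.shape[0]):
        tied = classes[scores[row] >= best[row] - 1e-12]
        for c in tie_order:
            if c in tied:
                predictions[row] = c
                break
    return predictions


def tune_knn(
    coords,
    classes,
    grid: Mapping[str, Sequence] | Sequence[KnnConfig] | None = None,
    folds: int = 10,
    seed: int | None = None,
) -> tuple[KnnConfig, float]:
    """Select knn hyperparameters by stratified k-fold cross-validation.

    ``grid`` is either a mapping with keys among ``k``, ``minkowski_p``,
    ``kernel`` (cartesian product taken) or an explicit list of configs.
    Best = highest mean CV accuracy; ties resolved toward smaller ``k``,
    then smaller ``minkowski_p``.  Reproducible from ``seed``.
    """
    X = np.asarray(coords, dtype=float)
    y = np.asarray(classes)
    if X.shape[0] < folds:
        raise ValueError(f"{folds}-fold CV needs at least {folds} specimens")
    if grid is None:
        grid = {"k": [5, 10], "minkowski_p": [2.0, 4.0], "kernel": ["optimal"]}
    if isinstance(grid, Mapping):
        configs = [
            KnnConfig(k=int(k), minkowski_p=float(p), kernel=str(kern),
                      folds=folds, seed=seed)
            for k, p, kern in product(
                grid.get("k", [10]),
                grid.get("minkowski_p", [2.0]),
                grid.get("kernel", ["optimal"]),
            )
        ]
    else:
        configs = [replace(c, folds=folds, seed=seed) for c in grid]
    if not configs:
        raise ValueError("empty tuning grid")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    try:
        splits = list(skf.split(X, y))
    except ValueError as exc:
        raise ValueError(
            f"a class would be absent from some training split: {exc}"
        ) from exc
    all_classes = set(np.unique(y))
    for train_idx, _ in splits:
        missing = all_classes - set(np.unique(y[train_idx]))
        if missing:
            raise ValueError(
                f"class {missing.pop()!r} absent from a training split; "
                "use fewer folds or more specimens"
            )

    results: list[tuple[float, KnnConfig]] = []
    for cfg in configs:
        hits = 0
        for train_idx, test_idx in splits:
            k_eff = min(cfg.k, len(train_idx))
            cfg_eff = replace(cfg, k=k_eff)
            pred = knn_predict(X[train_idx], y[train_idx], X[test_idx], cfg_eff)
            hits += int((pred == y[test_idx]).sum())
        results.append((hits / X.shape[0], cfg))

    best_accuracy = max(acc for acc, _ in results)
    contenders = [cfg for acc, cfg in results if acc >= best_accuracy - 1e-12]
    best = min(contenders, key=lambda c: (c.k, c.minkowski_p, KERNELS.index(c.kernel)))
    return best, best_accuracy


@dataclass(frozen=True)
class ConfusionPartition:
    """Specimen assignments to the four diagnostic categories."""

    tn_members: tuple[int, ...]
    fn_members: tuple[int, ...]
    tp_members: tuple[int, ...]
    fp_members: tuple[int, ...]

    tn: int = field(init=False)
    fn: int = field(init=False)
    tp: int = field(init=False)
    fp: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tn", len(self.tn_members))
        object.__setattr__(self, "fn", len(self.fn_members))
        object.__setattr__(self, "tp", len(self.tp_members))
        object.__setattr__(self, "fp", len(self.fp_members))

    @classmethod
    def from_counts(cls, tn: int, fn: int, tp: int, fp: int) -> "ConfusionPartition":
        """Build from printed counts alone (member indices are synthetic)."""
        bounds = np.cumsum([0, tn, fn, tp, fp])
        ids = [tuple(range(bounds[i], bounds[i + 1])) for i in range(4)]
        return cls(*ids)

    @property
    def total(self) -> int:
        return self.tn + self.fn + self.tp + self.fp

    def to_series(self) -> pd.Series:
        return pd.Series({"TN": self.tn, "FN": self.fn,
                          "TP": self.tp, "FP": self.fp})

    def category_of(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for cat, members in (("TN", self.tn_members), ("FN", self.fn_members),
                             ("TP", self.tp_members), ("FP", self.fp_members)):
            out.update({i: cat for i in members})
        return out


def partition_confusion(true_classes, predicted_classes) -> ConfusionPartition:
    """Cross observed and predicted yield classes into TN/FN/TP/FP.

    Convention: positive = low yielder.  TN = both high; TP = both low;
    FN = predicted high but observed low; FP = predicted low but observed high.
    """
    t = np.asarray(true_classes)
    p = np.asarray(predicted_classes)
    if t.shape != p.shape:
        raise ValueError("true and predicted class vectors differ in length")
    bad = (set(np.unique(t)) | set(np.unique(p))) - {HIGH, LOW}
    if bad:
        raise ValueError(f"unknown class labels {sorted(bad)}")
    idx = np.arange(t.size)
    return ConfusionPartition(
        tn_members=tuple(idx[(t == HIGH) & (p == HIGH)]),
        fn_members=tuple(idx[(t == LOW) & (p == HIGH)]),
        tp_members=tuple(idx[(t == LOW) & (p == LOW)]),
        fp_members=tuple(idx[(t == HIGH) & (p == LOW)]),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def diagnostic_metrics(cp: ConfusionPartition) -> dict[str, float]:
    """Accuracy, predictive values, sensitivity and specificity.

    Undefined ratios (zero denominator) are reported as NaN, never as 0.
    """
    if cp.total == 0:
        raise ValueError("empty confusion partition")
    return {
        "accuracy": (cp.tn + cp.tp) / cp.total,
        "npv": _ratio(cp.tn, cp.tn + cp.fn),
        "ppv": _ratio(cp.tp, cp.tp + cp.fp),
        "sensitivity": _ratio(cp.tp, cp.tp + cp.fn),
        "specificity": _ratio(cp.tn, cp.tn + cp.fp),
    }
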