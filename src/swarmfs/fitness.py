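"""Subset fitness: balanced classification error plus a sparsity term.

A continuous particle position is decoded to a boolean feature mask by
thresholding; the mask is scored with

    fitness = alpha_f * gammaR + (1 - alpha_f) * |S| / |N|,
    gammaR  = 1 - (1/C) * sum_i TPR_i,

where gammaR is the balanced error of a plug-in classifier under stratified
cross-validation on the training partition, |S| the subset size and |N| the
full dimensionality.  alpha_f defaults to 0.999999 so accuracy dominates and
sparsity only breaks ties.  Lower is better; an empty subset scores the
worst possible 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "EvalConfig",
    "ClassMetrics",
    "decode_mask",
    "balanced_error",
    "evaluate_subset",
    "SubsetEvaluator",
    "OneNearestNeighbor",
]


@dataclass(frozen=True)
class EvalConfig:
    """Fitness trade-off, decode threshold, inner-CV folds and the classifier.

    ``classifier`` is anything exposing ``fit(X, y)`` / ``predict(X)``; ``None``
    selects the built-in vectorized 1-nearest-neighbor, the fast default for
    wrapper search.  Feature columns are z-scored with training-fold
    statistics before classification.
    """

    alpha_f: float = 0.999999
    decode_threshold: float = 0.6
    classifier: Any = None
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_f < 1.0:
            raise ValueError("alpha_f must lie in (0, 1)")
        if not 0.0 < self.decode_threshold < 1.0:
            raise ValueError("decode_threshold must lie in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class true-positive rates and the balanced error derived from them."""

    tpr_per_class: np.ndarray
    balanced_error: float
    n_classes: int


class OneNearestNeighbor:
    """Minimal 1-NN classifier honouring the fit/predict plug-in contract."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneNearestNeighbor":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d2 = (
            (X**2).sum(axis=1)[:, None]
            + (self._X**2).sum(axis=1)[None, :]
            - 2.0 * X @ self._X.T
        )
        return self._y[np.argmin(d2, axis=1)]


def decode_mask(
    position: np.ndarray, task_mask: np.ndarray, decode_threshold: float
) -> np.ndarray:
    """Threshold a continuous position into a boolean mask within the task."""
    position = np.asarray(position, dtype=float)
    task_mask = np.asarray(task_mask, dtype=bool)
    return (position > decode_threshold) & task_mask


def balanced_error(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> ClassMetrics:
    """Balanced error 1 - mean per-class TPR; every class must appear in y_true."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors have mismatched lengths")
    tpr = np.empty(n_classes)
    for c in range(n_classes):
        in_c = y_true == c
        if not in_c.any():
            raise ValueError(f"class {c} absent from true labels; TPR undefined")
        tpr[c] = np.count_nonzero(y_pred[in_c] == c) / np.count_nonzero(in_c)
    return ClassMetrics(tpr, float(1.0 - tpr.mean()), n_classes)


def _fold_balanced_error(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Balanced error over the classes present in this fold's truth."""
    classes = np.unique(y_true)
    tpr = [
        np.count_nonzero(y_pred[y_true == c] == c) / np.count_nonzero(y_true == c)
        for c in classes
    ]
    return float(1.0 - np.mean(tpr))


def _zscore_pair(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu) / sd


class SubsetEvaluator:
    """Mask-keyed, memoized fitness evaluator over a fixed training partition.

    Fold assignments are frozen at construction (seeded stratified k-fold), so
    the same mask always maps to the identical fitness — the memoization
    contract the wrapper search relies on.  When the smallest class is smaller
    than the requested fold count, the fold count is reduced with a warning.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: EvalConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.config = config or EvalConfig()
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("data and labels disagree on the number of samples")
        self.d = self.X.shape[1]
        smallest = int(np.bincount(self.y).min())
        folds = self.config.inner_folds
        if smallest < folds:
            warnings.warn(
                f"smallest class has {smallest} samples; reducing inner folds "
                f"from {folds} to {max(smallest, 2)}",
                stacklevel=2,
            )
            folds = max(smallest, 2)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
        self.folds = [
            (tr.copy(), te.copy()) for tr, te in skf.split(self.X, self.y)
        ]
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0
        self.cache_hits = 0

    def cross_validated_error(self, mask: np.ndarray) -> float:
        """Mean balanced error of the plug-in classifier over the inner folds."""
        Xm = self.X[:, mask]
        clf = self.config.classifier
        errs = []
        for tr, te in self.folds:
            Xtr, Xte = _zscore_pair(Xm[tr], Xm[te])
            if clf is None:
                # fast path: BLAS-backed 1-NN, identical in result to
                # OneNearestNeighbor().fit(Xtr, ytr).predict(Xte)
                d2 = (
                    (Xte**2).sum(axis=1)[:, None]
                    + (Xtr**2).sum(axis=1)[None, :]
                    - 2.0 * Xte @ Xtr.T
                )
                pred = self.y[tr][np.argmin(d2, axis=1)]
            else:
                model = _fresh(clf)
                model.fit(Xtr, self.y[tr])
                pred = np.asarray(model.predict(Xte))
            errs.append(_fold_balanced_error(self.y[te], pred))
        return float(np.mean(errs))

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.d:
            raise ValueError("mask length does not match the dataset")
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            self.cache_hits += 1
            return hit
        count = int(np.count_nonzero(mask))
        if count == 0:
            fit = 1.0  # degenerate empty subset: worst possible
        else:
            gamma = self.cross_validated_error(mask)
            a = self.config.alpha_f
            fit = a * gamma + (1.0 - a) * count / self.d
        self._cache[key] = fit
        self.n_evaluations += 1
        return fit


def _fresh(classifier: Any) -> Any:
    """A new unfitted copy of a plug-in classifier."""
    try:
        from sklearn.base import clone

        return clone(classifier)
    except Exception:
        import copy

        return copy.deepcopy(classifier)


def evaluate_subset(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    config: EvalConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """One-off fitness of a mask; ``rng`` seeds the inner-CV fold shuffle."""
    seed = int(rng.integers(2**31)) if rng is not None else 0
    return SubsetEvaluator(X, y, config, seed=seed)(np.asarray(mask, dtype=bool))
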