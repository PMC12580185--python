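"""Filter scoring, score fusion, knee-point thresholding and dual-task construction.

Two complementary relevance filters are computed per feature: Relief-F
(neighborhood-based instance discrimination) and the Fisher score
(between-class over within-class variance).  After min-max normalization the
two are fused linearly,

    w_i = alpha * w_i^RF + beta * w_i^FS,

the fused scores are ranked in descending order, and the knee of the ranked
curve — the point at maximum perpendicular distance from the chord joining
the curve's endpoints — sets an adaptive cut-off.  Features at or above the
knee define the compact auxiliary search task; the primary task keeps the
full feature set.  Pearson-correlation and total-variance scorers are
provided as ablation alternatives for the fusion step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ScoringConfig",
    "KneeResult",
    "TaskPair",
    "compute_fisher_score",
    "compute_relief_f",
    "compute_pcc_score",
    "compute_variance_score",
    "normalize_scores",
    "fuse_scores",
    "detect_knee",
    "generate_tasks",
    "score_table",
]

#: denominator stabilizer for the Fisher score (zero within-class variance)
FISHER_EPS = 1e-12


@dataclass(frozen=True)
class ScoringConfig:
    """Weights of the linear fusion and Relief-F parameters.

    alpha/beta weight Relief-F and Fisher after each is min-max normalized;
    equal weights are the neutral default.  ``relief_neighbors`` is clamped
    per class to (class size - 1) hits / class size misses when a class is
    small.  ``relief_samples`` is the number of instances sampled ("all"
    iterates every instance deterministically).
    """

    alpha: float = 0.5
    beta: float = 0.5
    relief_neighbors: int = 10
    relief_samples: int | str = "all"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha + self.beta <= 0:
            raise ValueError("alpha + beta must be positive")
        if self.relief_neighbors < 1:
            raise ValueError("relief_neighbors must be a positive integer")
        if self.relief_samples != "all" and int(self.relief_samples) < 1:
            raise ValueError("relief_samples must be 'all' or a positive integer")


@dataclass(frozen=True)
class KneeResult:
    """Knee of a descending score curve: 0-based index, score there, and the
    number of features at or above it (the knee feature is included)."""

    knee_index: int
    threshold_score: float
    selected_count: int


@dataclass
class TaskPair:
    """The dual search tasks over one dataset.

    The primary mask is all-true (global search); the auxiliary mask marks
    the knee-selected candidate subset.  ``ranking`` lists feature indices in
    descending fused-score order (ties broken by original index).
    """

    primary_mask: np.ndarray
    auxiliary_mask: np.ndarray
    combined_scores: np.ndarray
    ranking: np.ndarray
    knee: KneeResult


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("data and labels disagree on the number of samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite entries")
    if np.unique(y).size < 2:
        raise ValueError("need >=2 classes")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return X, y


def compute_fisher_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher score per feature: between-class scatter over within-class scatter.

    F_j = sum_c n_c (mu_cj - mu_j)^2 / (sum_c n_c sigma^2_cj + eps), with
    population (ddof=0) within-class variances.  Constant features score 0.
    """
    X, y = _validate_xy(X, y)
    classes = np.unique(y)
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        nc = Xc.shape[0]
        num += nc * (Xc.mean(axis=0) - mu) ** 2
        den += nc * Xc.var(axis=0)
    return num / (den + FISHER_EPS)


def _minmax_columns(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0  # constant columns scale to all-zeros
    return (X - lo) / span


def compute_relief_f(
    X: np.ndarray,
    y: np.ndarray,
    config: ScoringConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Relief-F feature weights (Kononenko's multi-class form).

    Features are min-max scaled to [0, 1] internally so per-feature diffs are
    commensurate; instance distances are Manhattan on the scaled features.
    For each sampled instance the averaged diffs to its k nearest same-class
    hits are subtracted and the class-prior-weighted averaged diffs to the k
    nearest misses of every other class are added; weights are normalized by
    the number of sampled instances.  Neighbor ties break on sample index.
    """
    config = config or ScoringConfig()
    X, y = _validate_xy(X, y)
    n, d = X.shape
    Xs = _minmax_columns(X)

    if config.relief_samples == "all":
        sampled = np.arange(n)
    else:
        m = min(int(config.relief_samples), n)
        if rng is None:
            rng = np.random.default_rng(0)
        sampled = rng.choice(n, size=m, replace=False)

    classes = np.unique(y)
    priors = {c: np.count_nonzero(y == c) / n for c in classes}
    by_class = {c: np.flatnonzero(y == c) for c in classes}
    dist = cdist(Xs, Xs, metric="cityblock")

    k = config.relief_neighbors
    w = np.zeros(d)
    for i in sampled:
        ci = y[i]
        hits = by_class[ci][by_class[ci] != i]
        if hits.size:
            kh = min(k, hits.size)
            nearest = hits[np.argsort(dist[i, hits], kind="stable")[:kh]]
            w -= np.abs(Xs[i] - Xs[nearest]).mean(axis=0)
        for c in classes:
            if c == ci:
                continue
            idx = by_class[c]
            km = min(k, idx.size)
            nearest = idx[np.argsort(dist[i, idx], kind="stable")[:km]]
            w += (priors[c] / (1.0 - priors[ci])) * np.abs(
                Xs[i] - Xs[nearest]
            ).mean(axis=0)
    return w / sampled.size


def compute_pcc_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation of each feature with the integer-coded label.

    Zero-variance features score 0 by definition.
    """
    X, y = _validate_xy(X, y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    num = Xc.T @ yc
    out = np.zeros(X.shape[1])
    nz = denom > 0
    out[nz] = np.abs(num[nz] / denom[nz])
    return out


def compute_variance_score(X: np.ndarray) -> np.ndarray:
    """Per-feature sample variance (ddof=1); a label-free baseline scorer."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite entries")
    return X.var(axis=0, ddof=1)


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to all zeros."""
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain non-finite values")
    span = s.max() - s.min()
    if span == 0:
        return np.zeros_like(s)
    return (s - s.min()) / span


def fuse_scores(
    w_rf: np.ndarray, w_fs: np.ndarray, config: ScoringConfig | None = None
) -> np.ndarray:
    """Weighted linear fusion of two (already normalized) score vectors."""
    config = config or ScoringConfig()
    w_rf = np.asarray(w_rf, dtype=float)
    w_fs = np.asarray(w_fs, dtype=float)
    if w_rf.shape != w_fs.shape:
        raise ValueError("score vectors have mismatched lengths")
    return config.alpha * w_rf + config.beta * w_fs


def detect_knee(sorted_scores: np.ndarray) -> KneeResult:
    """Knee of a non-increasing score curve by maximum chord distance.

    The chord runs from (0, s_0) to (d-1, s_{d-1}); the knee is the point at
    maximum perpendicular distance from it (ties -> smallest index).  When
    every point is collinear with the chord there is no knee; the fallback
    selects the top ceil(d/2) features.
    """
    s = np.asarray(sorted_scores, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("need a 1-D curve of length >= 2")
    if np.any(np.diff(s) > 0):
        raise ValueError("scores must be sorted in non-increasing order")
    d = s.size
    x = np.arange(d, dtype=float)
    dy = s[-1] - s[0]
    dx = float(d - 1)
    # distance from (x_i, s_i) to the chord, up to the common 1/hypot factor
    dist = np.abs(dy * x - dx * (s - s[0]))
    scale = max(1.0, abs(dy))
    if dist.max() <= 1e-12 * scale:
        count = math.ceil(d / 2)
        return KneeResult(count - 1, float(s[count - 1]), count)
    knee = int(np.argmax(dist))
    return KneeResult(knee, float(s[knee]), knee + 1)


def generate_tasks(
    X: np.ndarray,
    y: np.ndarray,
    config: ScoringConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TaskPair:
    """Score, fuse, rank, find the knee and emit the dual-task definition.

    Deterministic given (data, labels, rng state); ranking ties break by
    original feature index (stable sort).
    """
    config = config or ScoringConfig()
    X, y = _validate_xy(X, y)
    d = X.shape[1]
    w_rf = normalize_scores(compute_relief_f(X, y, config, rng))
    w_fs = normalize_scores(compute_fisher_score(X, y))
    fused = fuse_scores(w_rf, w_fs, config)
    ranking = np.argsort(-fused, kind="stable")
    knee = detect_knee(fused[ranking])
    count = min(knee.selected_count, d - 1)  # auxiliary task is a strict subset
    aux = np.zeros(d, dtype=bool)
    aux[ranking[:count]] = True
    return TaskPair(
        primary_mask=np.ones(d, dtype=bool),
        auxiliary_mask=aux,
        combined_scores=fused,
        ranking=ranking,
        knee=knee,
    )


def score_table(tasks: TaskPair, feature_names: list[str] | None = None):
    """Ranked fused-score curve as a DataFrame (rank, feature, score, at/above knee).

    Suitable for plotting the score curve with its knee marked.
    """
    import pandas as pd

    idx = tasks.ranking
    names = (
        [feature_names[j] for j in idx]
        if feature_names
        else [f"f{j}" for j in idx]
    )
    return pd.DataFrame(
        {
            "rank": np.arange(idx.size),
            "feature_index": idx,
            "feature": names,
            "score": tasks.combined_scores[idx],
            "selected": np.arange(idx.size) < tasks.knee.selected_count,
        }
    )
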