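"""Labeled datasets: synthetic generators with planted signal, and delimited-table I/O.

High-dimensional omics classification problems typically have far more
features than samples (d of a few thousand against n below a few hundred),
with a small informative core, correlated redundant copies of that core, and
a large majority of pure-noise features.  :func:`make_synthetic_dataset`
emulates exactly that regime so the whole selection pipeline can be exercised
and scored against a known ground truth without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "LabeledDataset",
    "make_synthetic_dataset",
    "benchmark_spec",
    "informative_recall",
    "read_labeled_table",
    "write_labeled_table",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-signal d >> n classification dataset.

    ``class_sep`` is the distance between the means of adjacent classes on
    each informative feature, in units of the unit noise SD.  Redundant
    features are noisy copies of randomly chosen informative features with
    additive ``Normal(0, redundant_noise_sd)`` jitter.  All remaining
    features are label-independent standard normal noise.
    """

    n_samples: int = 120
    n_features: int = 500
    n_informative: int = 10
    n_redundant: int = 20
    n_classes: int = 3
    class_sep: float = 2.0
    redundant_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 0 or self.n_redundant < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("n_informative + n_redundant exceeds n_features")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("need n_samples >= 2 * n_classes")
        if self.class_sep <= 0:
            raise ValueError("class_sep must be positive")
        if self.redundant_noise_sd < 0:
            raise ValueError("redundant_noise_sd must be non-negative")


@dataclass
class LabeledDataset:
    """An n x d numeric matrix with integer class labels.

    ``informative`` / ``redundant`` hold ground-truth feature indices when the
    dataset is synthetic; they are ``None`` for data read from disk.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)
    informative: np.ndarray | None = None
    redundant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if not self.class_names:
            self.class_names = [str(c) for c in np.unique(self.y)]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.y).size)


def _balanced_labels(n_samples: int, n_classes: int) -> np.ndarray:
    """Class labels as balanced as n allows (counts differ by at most 1)."""
    base = n_samples // n_classes
    extra = n_samples % n_classes
    counts = [base + (1 if c < extra else 0) for c in range(n_classes)]
    return np.repeat(np.arange(n_classes), counts)


def make_synthetic_dataset(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> LabeledDataset:
    """Generate a planted-signal dataset, fully determined by the seed.

    Informative feature j of a class-c sample is ``Normal(c * class_sep * u_j, 1)``
    with a fixed per-feature sign ``u_j`` in {-1, +1}; redundant features are
    noisy copies of random informative ones; everything else is ``Normal(0, 1)``.
    Column positions of the planted features are scattered uniformly and rows
    are shuffled, so nothing can be recovered from ordering alone.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    ni, nr = spec.n_informative, spec.n_redundant

    y = _balanced_labels(n, spec.n_classes)

    # Fixed draw order: column placement, signs, base noise, redundant
    # sources/jitter, row shuffle.  Changing it changes every seeded dataset.
    placement = rng.permutation(d)
    informative = np.sort(placement[:ni])
    redundant = np.sort(placement[ni : ni + nr])
    signs = rng.choice([-1.0, 1.0], size=ni)

    X = rng.standard_normal((n, d))
    for k, col in enumerate(informative):
        X[:, col] += y * spec.class_sep * signs[k]
    if nr:
        sources = rng.integers(0, ni, size=nr) if ni else None
        if sources is None:
            raise ValueError("redundant features require n_informative >= 1")
        jitter = rng.standard_normal((n, nr)) * spec.redundant_noise_sd
        for k, col in enumerate(redundant):
            X[:, col] = X[:, informative[sources[k]]] + jitter[:, k]

    order = rng.permutation(n)
    return LabeledDataset(
        X=X[order],
        y=y[order],
        informative=informative,
        redundant=redundant,
    )


def benchmark_spec(seed: int = 1) -> SyntheticSpec:
    """The frozen desk-scale benchmark used throughout the test suite."""
    return SyntheticSpec(seed=seed)


def informative_recall(mask: np.ndarray, informative: Sequence[int]) -> float:
    """Fraction of ground-truth informative features captured by ``mask``.

    Recall ignores precision: a mask selecting every feature scores 1.0.
    Returns ``nan`` when the truth set is empty.
    """
    mask = np.asarray(mask, dtype=bool)
    truth = np.asarray(informative, dtype=int)
    if truth.size == 0:
        return float("nan")
    return float(np.count_nonzero(mask[truth]) / truth.size)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_labeled_table(path: str | Path, label_column: str = "label") -> LabeledDataset:
    """Read a delimited table (one row per sample) into a :class:`LabeledDataset`.

    Every non-label column must be numeric and complete; labels are coded as
    integers 0..C-1 in sorted order of the distinct label values, with the
    original values kept in ``class_names``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(
            f"label column {label_column!r} not found in {path.name} "
            f"(columns: {list(df.columns)[:8]}...)"
        )
    labels = df[label_column]
    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        vals = pd.to_numeric(feats[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric or missing value at row {row}, column {col!r}"
            )
        feats[col] = vals
    classes = sorted(pd.unique(labels), key=str)
    code = {c: i for i, c in enumerate(classes)}
    y = labels.map(code).to_numpy(dtype=int)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes in the label column")
    return LabeledDataset(
        X=feats.to_numpy(dtype=float),
        y=y,
        feature_names=[str(c) for c in feats.columns],
        class_names=[str(c) for c in classes],
    )


def write_labeled_table(
    dataset: LabeledDataset, path: str | Path, label_column: str = "label"
) -> None:
    """Write the dataset in the same layout :func:`read_labeled_table` consumes."""
    path = Path(path)
    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    names = np.asarray(dataset.class_names, dtype=object)
    df[label_column] = names[dataset.y]
    # %.17g guarantees exact float round-trip through text
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
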