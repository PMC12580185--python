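"""Outer evaluation protocol: per-fold selection, repeated runs, paired tests.

Feature selection is performed separately inside each outer training fold —
task construction, search and fitness evaluation see training rows only —
and the resulting subset is scored on the held-out fold, so no information
leaks from test data into selection.  The harness instruments that boundary:
every row access during the selection phase is recorded and any held-out row
read is counted in the report (it must be zero).  Runs repeat over derived
seeds (base_seed + run index) and variants are compared pairwise with the
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledDataset
from .engine import TransferConfig, run_feature_selection
from .fitness import EvalConfig, OneNearestNeighbor, _fresh, _zscore_pair
from .scoring import ScoringConfig

__all__ = [
    "ExperimentConfig",
    "BenchmarkReport",
    "outer_evaluate",
    "compare_variants",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Outer-protocol settings: folds, repeats, variant and module configs."""

    outer_folds: int = 10
    n_runs: int = 30
    variant: str = "ec_pso_transfer"
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    transfer: TransferConfig = field(default_factory=TransferConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class BenchmarkReport:
    """Per-run held-out metrics for one algorithm variant.

    Accuracies are percentages; ``balanced_accuracy`` is 100*(1 - balanced
    error), the metric matching the fitness function, with plain accuracy
    reported alongside.  ``held_out_row_reads`` counts data-matrix row reads
    of held-out samples during the selection phase (protocol hygiene: 0).
    """

    variant: str
    per_run_balanced_accuracy: np.ndarray
    per_run_plain_accuracy: np.ndarray
    per_run_subset_size: np.ndarray
    held_out_row_reads: int
    config: ExperimentConfig

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, vals in [
            ("balanced_accuracy_pct", self.per_run_balanced_accuracy),
            ("plain_accuracy_pct", self.per_run_plain_accuracy),
            ("subset_size", self.per_run_subset_size),
        ]:
            rows.append(
                {
                    "metric": name,
                    "mean": float(np.mean(vals)),
                    "std": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n_runs": len(vals),
                }
            )
        return pd.DataFrame(rows)


class _RowLogMatrix(np.ndarray):
    """ndarray view that records first-axis indices touched while active."""

    def __array_finalize__(self, obj):
        if obj is not None:
            self.accessed = getattr(obj, "accessed", None)
            self.active = getattr(obj, "active", None)

    def __getitem__(self, item):
        if self.accessed is not None and self.active and self.active[0]:
            rows = item[0] if isinstance(item, tuple) else item
            if isinstance(rows, (int, np.integer)):
                self.accessed.add(int(rows))
            elif isinstance(rows, (np.ndarray, list)):
                arr = np.asarray(rows)
                if arr.dtype == bool:
                    arr = np.flatnonzero(arr)
                self.accessed.update(int(r) for r in arr.ravel())
            elif isinstance(rows, slice):
                self.accessed.update(range(*rows.indices(self.shape[0])))
        return super().__getitem__(item)


def _holdout_score(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    yte: np.ndarray,
    mask: np.ndarray,
    eval_config: EvalConfig,
) -> tuple[float, float]:
    """(balanced error, plain error) of the final classifier on held-out rows."""
    if not mask.any():
        return 1.0, 1.0
    A, B = _zscore_pair(Xtr[:, mask], Xte[:, mask])
    clf = eval_config.classifier
    model = OneNearestNeighbor() if clf is None else _fresh(clf)
    model.fit(A, ytr)
    pred = np.asarray(model.predict(B))
    classes = np.unique(yte)
    tpr = [
        np.count_nonzero(pred[yte == c] == c) / np.count_nonzero(yte == c)
        for c in classes
    ]
    return float(1.0 - np.mean(tpr)), float(np.mean(pred != yte))


def outer_evaluate(
    dataset: LabeledDataset, config: ExperimentConfig | None = None
) -> BenchmarkReport:
    """Run the outer protocol and aggregate per-run held-out metrics."""
    config = config or ExperimentConfig()
    n_folds = config.outer_folds
    smallest = int(np.bincount(dataset.y).min())
    if smallest < n_folds:
        warnings.warn(
            f"smallest class has {smallest} samples; reducing outer folds "
            f"from {n_folds} to {max(smallest, 2)}",
            stacklevel=2,
        )
        n_folds = max(smallest, 2)

    accessed: set[int] = set()
    active = [False]
    Xlog = dataset.X.view(_RowLogMatrix)
    Xlog.accessed = accessed
    Xlog.active = active

    bal_acc, plain_acc, sizes = [], [], []
    held_out_reads = 0
    for run in range(config.n_runs):
        seed = config.base_seed + run
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % 2**31)
        fold_bal, fold_plain, fold_sizes = [], [], []
        for tr, te in skf.split(dataset.X, dataset.y):
            accessed.clear()
            active[0] = True
            Xtr = np.asarray(Xlog[tr])  # selection sees a training-rows copy only
            train = LabeledDataset(X=Xtr, y=dataset.y[tr])
            result = run_feature_selection(
                train,
                scoring_config=config.scoring,
                transfer_config=config.transfer,
                eval_config=config.eval,
                rng=np.random.default_rng(seed),
                variant=config.variant,
            )
            active[0] = False
            held_out_reads += len(accessed.intersection(te.tolist()))
            gamma, plain = _holdout_score(
                dataset.X[tr],
                dataset.y[tr],
                dataset.X[te],
                dataset.y[te],
                result.best_mask,
                config.eval,
            )
            fold_bal.append(100.0 * (1.0 - gamma))
            fold_plain.append(100.0 * (1.0 - plain))
            fold_sizes.append(result.n_selected)
        bal_acc.append(float(np.mean(fold_bal)))
        plain_acc.append(float(np.mean(fold_plain)))
        sizes.append(float(np.mean(fold_sizes)))

    return BenchmarkReport(
        variant=config.variant,
        per_run_balanced_accuracy=np.asarray(bal_acc),
        per_run_plain_accuracy=np.asarray(plain_acc),
        per_run_subset_size=np.asarray(sizes),
        held_out_row_reads=held_out_reads,
        config=config,
    )


def compare_variants(
    reports: Mapping[str, BenchmarkReport] | Iterable[BenchmarkReport],
    alpha: float = 0.05,
    metric: str = "balanced_accuracy",
) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank calls on paired per-run values.

    Per pair (a, b): '+' when a is significantly better at level ``alpha``,
    '-' when significantly worse, '=' otherwise (including identical runs).
    """
    if not isinstance(reports, Mapping):
        reports = {r.variant: r for r in reports}
    names = list(reports)
    if len(names) < 2:
        raise ValueError("need at least two reports to compare")
    attr = f"per_run_{metric}"
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va = getattr(reports[a], attr)
            vb = getattr(reports[b], attr)
            if len(va) != len(vb):
                raise ValueError(f"unpaired run counts for {a!r} vs {b!r}")
            diff = va - vb
            if np.all(diff == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(va, vb).pvalue)
            if p >= alpha:
                call = "="
            else:
                call = "+" if np.mean(diff) > 0 else "-"
            rows.append({"a": a, "b": b, "p_value": p, "call": call})
    return pd.DataFrame(rows)
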