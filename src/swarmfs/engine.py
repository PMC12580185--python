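"""Dual-task engine: four-mode loser updates, cross-task elite transfer, main loop.

Two swarms — one over the full feature space, one over the knee-selected
candidate subset — evolve by pairwise competition.  Each loser picks one of
four velocity updates via two independent Bernoulli draws (transfer with
probability p_trans, elite learning with probability p_k):

    cross & elite   : V <- r1*V + r2*(E_own - X) + r3*(E_other - X)
    cross & ~elite  : V <- r1*V + r2*(W_own - X) + r3*(W_other - X)
    ~cross & elite  : V <- r1*V + r2*(E_own - X) + phi*r3*(Ebar_own - X)
    ~cross & ~elite : V <- r1*V + r2*(W_own - X) + phi*r3*(Xbar - X)

with E_* uniformly random elite-pool members, W_own the pair's winner, and
W_other a uniformly random winner of the other task.  Both tasks share the
full d-dimensional representation; the auxiliary task pins non-candidate
dimensions to zero, which keeps cross-task vectors dimension-consistent.

Per-loser randomness follows a fixed draw order — mode draws (u1, u2), then
the coefficient vectors r1, r2, r3, then any source-selection draws — so a
seeded run is exactly reproducible and every ablation variant consumes the
stream identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .datasets import LabeledDataset
from .fitness import EvalConfig, SubsetEvaluator, decode_mask
from .scoring import ScoringConfig, TaskPair, generate_tasks
from .swarm import (
    ElitePool,
    Particle,
    Swarm,
    classical_loser_update,
    init_swarm,
    pair_particles,
    select_elites,
)

__all__ = [
    "TransferConfig",
    "UpdateMode",
    "RunResult",
    "choose_update_mode",
    "transfer_update",
    "run_search",
    "run_feature_selection",
    "run_ablation_variant",
    "VARIANTS",
]

logger = logging.getLogger("swarmfs")

VARIANTS = ("plain_cso", "ec_pso", "ec_pso_transfer")


@dataclass(frozen=True)
class TransferConfig:
    """Search-budget and transfer parameters.

    Defaults: transfer and elite-learning probabilities 0.6, population 70,
    100 iterations per task; phi (centroid/elite-mean pull) 0.1 and a 10%
    elite fraction are package defaults, both configurable.
    """

    p_trans: float = 0.6
    p_k: float = 0.6
    phi: float = 0.1
    k_elite: int | None = None
    pop_size: int = 70
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_trans <= 1.0 or not 0.0 <= self.p_k <= 1.0:
            raise ValueError("p_trans and p_k must lie in [0, 1]")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")
        if self.k_elite is not None and self.k_elite < 1:
            raise ValueError("k_elite must be >= 1")

    def resolved_k_elite(self) -> int:
        return self.k_elite if self.k_elite is not None else math.ceil(
            0.1 * self.pop_size
        )


@dataclass(frozen=True)
class UpdateMode:
    """One of the four loser-update modes (cross-task x elite)."""

    cross_task: bool
    elite: bool


@dataclass
class RunResult:
    """Outcome of one seeded search run.

    ``history`` holds the per-generation best fitness per task (row 0 is the
    initial population); ``best_so_far`` is the non-increasing global record.
    """

    best_mask: np.ndarray
    best_fitness: float
    best_task: int
    history: np.ndarray
    best_so_far: np.ndarray
    n_evaluations: int
    cross_reads: int
    config: TransferConfig
    tasks: TaskPair | None = None

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.best_mask))


def choose_update_mode(
    rng: np.random.Generator, config: TransferConfig
) -> UpdateMode:
    """Two independent U[0,1] draws: cross-task iff u1 < p_trans, elite iff u2 < p_k."""
    u1 = rng.random()
    u2 = rng.random()
    return UpdateMode(cross_task=u1 < config.p_trans, elite=u2 < config.p_k)


def transfer_update(
    loser: Particle,
    mode: UpdateMode,
    own_winner: Particle,
    own_elites: ElitePool,
    other_elites: ElitePool | None,
    other_winners: Sequence[Particle] | None,
    own_swarm_mean: np.ndarray,
    config: TransferConfig,
    rng: np.random.Generator,
    task_mask: np.ndarray,
    *,
    coeffs=None,
) -> Particle:
    """Apply the four-mode velocity update to one loser.

    Draw order after the (externally drawn) mode: r1, r2, r3 coefficient
    vectors, then source-selection integers (own elite before other-task
    source).  The returned particle is clamped and re-zeroed outside the
    loser's own candidate dimensions.
    """
    from .swarm import _draw_coeffs, _finish_update

    d = loser.position.size
    x = loser.position
    r1, r2, r3 = _draw_coeffs(rng, d, coeffs)
    inertia = r1 * loser.velocity

    if mode.elite:
        if own_elites is None or not own_elites.members:
            raise ValueError("elite pool required for an elite update mode")
        own_src = own_elites.members[rng.integers(len(own_elites.members))].position
    else:
        own_src = own_winner.position

    if mode.cross_task:
        if mode.elite:
            if other_elites is None or not other_elites.members:
                raise ValueError("elite pool required for an elite update mode")
            other_src = other_elites.members[
                rng.integers(len(other_elites.members))
            ].position
        else:
            if not other_winners:
                raise ValueError("other-task winners required for cross-task mode")
            other_src = other_winners[rng.integers(len(other_winners))].position
        v = inertia + r2 * (own_src - x) + r3 * (other_src - x)
    else:
        pull = own_elites.elite_mean if mode.elite else own_swarm_mean
        v = inertia + r2 * (own_src - x) + config.phi * r3 * (pull - x)

    return _finish_update(x.copy(), v, np.asarray(task_mask, bool))


def _evaluate(
    swarm: Swarm, objective: Callable[[np.ndarray], float], threshold: float
) -> None:
    for p in swarm.particles:
        if p.fitness is None:
            p.fitness = objective(decode_mask(p.position, swarm.task_mask, threshold))


def run_search(
    objective: Callable[[np.ndarray], float],
    task_masks: Sequence[np.ndarray],
    config: TransferConfig,
    rng: np.random.Generator,
    decode_threshold: float = 0.6,
    callback: Callable[[int, list[Swarm]], None] | None = None,
) -> RunResult:
    """Run the dual-task (or single-task) competitive search loop.

    Per generation: recompute each task's elite pool from the current swarm,
    randomly pair each swarm, then update losers task by task — each via a
    freshly drawn update mode.  Winners and odd leftovers pass through
    unchanged.  Cross-task modes read only the other task's elite copies and
    current winners, never its live particles.  A best-so-far record is kept
    outside the swarms, so the reported optimum never regresses.
    """
    n_tasks = len(task_masks)
    if n_tasks not in (1, 2):
        raise ValueError("run_search handles one or two tasks")
    swarms = [init_swarm(m, config.pop_size, rng) for m in task_masks]
    n_evals = 0
    cross_reads = 0
    for s in swarms:
        _evaluate(s, objective, decode_threshold)
        n_evals += s.pop_size

    best_fit = math.inf
    best_particle: Particle | None = None
    best_task = 0

    def _track(swarm: Swarm, t: int) -> None:
        nonlocal best_fit, best_particle, best_task
        for p in swarm.particles:
            if p.fitness < best_fit:
                best_fit = p.fitness
                best_particle = p.copy()
                best_task = t

    for t, s in enumerate(swarms):
        _track(s, t)
    history = [[float(s.fitness_values().min()) for s in swarms]]
    best_so_far = [best_fit]
    if callback is not None:
        callback(0, swarms)

    k = config.resolved_k_elite()
    for gen in range(1, config.max_iter + 1):
        pools = [select_elites(s, k) for s in swarms]
        means = [s.mean_position() for s in swarms]
        matchups = [pair_particles(s, rng) for s in swarms]
        for t, s in enumerate(swarms):
            other = 1 - t if n_tasks == 2 else None
            outcomes, _leftover = matchups[t]
            other_winners = (
                [
                    swarms[other].particles[o.winner_index]
                    for o in matchups[other][0]
                ]
                if other is not None
                else None
            )
            for o in outcomes:
                mode = choose_update_mode(rng, config)
                if mode.cross_task and other is None:
                    # single-task runs cannot transfer; fall back to intra-task
                    mode = UpdateMode(cross_task=False, elite=mode.elite)
                if mode.cross_task:
                    cross_reads += 1
                new = transfer_update(
                    s.particles[o.loser_index],
                    mode,
                    s.particles[o.winner_index],
                    pools[t],
                    pools[other] if other is not None else None,
                    other_winners,
                    means[t],
                    config,
                    rng,
                    s.task_mask,
                )
                new.fitness = objective(
                    decode_mask(new.position, s.task_mask, decode_threshold)
                )
                n_evals += 1
                s.particles[o.loser_index] = new
            _track(s, t)
        history.append([float(s.fitness_values().min()) for s in swarms])
        best_so_far.append(best_fit)
        if callback is not None:
            callback(gen, swarms)
        for t, s in enumerate(swarms):
            fv = s.fitness_values()
            sizes = [
                np.count_nonzero(
                    decode_mask(p.position, s.task_mask, decode_threshold)
                )
                for p in s.particles
            ]
            logger.debug(
                "gen=%d task=%d best=%.6g mean=%.6g mean_subset=%.1f",
                gen,
                t,
                fv.min(),
                fv.mean(),
                float(np.mean(sizes)),
            )

    assert best_particle is not None
    best_mask = decode_mask(
        best_particle.position, task_masks[best_task], decode_threshold
    )
    return RunResult(
        best_mask=best_mask,
        best_fitness=float(best_fit),
        best_task=best_task,
        history=np.asarray(history),
        best_so_far=np.asarray(best_so_far),
        n_evaluations=n_evals,
        cross_reads=cross_reads,
        config=config,
    )


def run_feature_selection(
    dataset: LabeledDataset,
    scoring_config: ScoringConfig | None = None,
    transfer_config: TransferConfig | None = None,
    eval_config: EvalConfig | None = None,
    rng: np.random.Generator | int | None = None,
    variant: str = "ec_pso_transfer",
) -> RunResult:
    """Full pipeline on a labeled dataset: dual-task construction + search.

    ``variant`` selects the full algorithm (``ec_pso_transfer``) or an
    ablation: ``ec_pso`` (two tasks, elite learning, no cross-task transfer,
    p_trans forced to 0) and ``plain_cso`` (single full-space task, classical
    updates only, p_trans = p_k = 0).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    scoring_config = scoring_config or ScoringConfig()
    transfer_config = transfer_config or TransferConfig()
    eval_config = eval_config or EvalConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    if variant == "plain_cso":
        transfer_config = replace(transfer_config, p_trans=0.0, p_k=0.0)
        tasks = None
        masks = [np.ones(dataset.n_features, dtype=bool)]
    else:
        if variant == "ec_pso":
            transfer_config = replace(transfer_config, p_trans=0.0)
        tasks = generate_tasks(dataset.X, dataset.y, scoring_config, rng)
        masks = [tasks.primary_mask, tasks.auxiliary_mask]

    evaluator = SubsetEvaluator(dataset.X, dataset.y, eval_config, seed=0)
    result = run_search(
        evaluator,
        masks,
        transfer_config,
        rng,
        decode_threshold=eval_config.decode_threshold,
    )
    result.tasks = tasks
    return result


def run_ablation_variant(variant: str, dataset: LabeledDataset, **kwargs) -> RunResult:
    """Named-variant entry point mirroring :func:`run_feature_selection`."""
    return run_feature_selection(dataset, variant=variant, **kwargs)
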