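"""Single-task competitive-swarm machinery.

Particles carry continuous positions in [0, 1]^d (decoded to feature masks
elsewhere).  Each generation the swarm is randomly split into pairs; the
better-fitness particle of a pair wins and survives unchanged, the loser
updates its velocity by learning from the winner and the swarm centroid,

    V <- r1*V + r2*(X_W - X_L) + phi*r3*(Xbar - X_L),   X <- X_L + V,

with r1, r2, r3 drawn per dimension.  A hierarchical elite pool (the top-K
lowest-fitness particles) is maintained per task as an alternative set of
learning exemplars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Particle",
    "Swarm",
    "ElitePool",
    "CompetitionOutcome",
    "init_swarm",
    "pair_particles",
    "classical_loser_update",
    "select_elites",
]


@dataclass
class Particle:
    """Position/velocity over all d dimensions; fitness ``None`` = unevaluated."""

    position: np.ndarray
    velocity: np.ndarray
    fitness: float | None = None

    def copy(self) -> "Particle":
        return Particle(self.position.copy(), self.velocity.copy(), self.fitness)


@dataclass
class Swarm:
    particles: list[Particle]
    task_mask: np.ndarray

    @property
    def pop_size(self) -> int:
        return len(self.particles)

    def mean_position(self) -> np.ndarray:
        return np.mean([p.position for p in self.particles], axis=0)

    def fitness_values(self) -> np.ndarray:
        return np.array(
            [math.inf if p.fitness is None else p.fitness for p in self.particles]
        )


@dataclass
class ElitePool:
    """Copies of the top-K lowest-fitness particles and their mean position."""

    members: list[Particle]
    elite_mean: np.ndarray
    k_elite: int


@dataclass(frozen=True)
class CompetitionOutcome:
    winner_index: int
    loser_index: int


def init_swarm(
    task_mask: np.ndarray, pop_size: int, rng: np.random.Generator
) -> Swarm:
    """Uniform positions on candidate dimensions, zero elsewhere; zero velocity.

    Draws one (pop_size, d) uniform block so the stream consumption does not
    depend on the mask.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    task_mask = np.asarray(task_mask, dtype=bool)
    positions = rng.random((pop_size, task_mask.size))
    positions[:, ~task_mask] = 0.0
    particles = [
        Particle(positions[i], np.zeros(task_mask.size)) for i in range(pop_size)
    ]
    return Swarm(particles, task_mask)


def pair_particles(
    swarm: Swarm, rng: np.random.Generator
) -> tuple[list[CompetitionOutcome], int | None]:
    """Uniform random perfect matching; per pair the lower fitness wins.

    Fitness ties break to the lower particle index.  With an odd population
    the last permuted particle is left over and passes through unchanged.
    """
    for i, p in enumerate(swarm.particles):
        if p.fitness is None:
            raise ValueError(f"particle {i} is unevaluated; cannot compete")
    perm = rng.permutation(swarm.pop_size)
    outcomes = []
    for a, b in zip(perm[0::2], perm[1::2]):
        fa, fb = swarm.particles[a].fitness, swarm.particles[b].fitness
        if (fa, a) <= (fb, b):
            outcomes.append(CompetitionOutcome(int(a), int(b)))
        else:
            outcomes.append(CompetitionOutcome(int(b), int(a)))
    leftover = int(perm[-1]) if swarm.pop_size % 2 else None
    return outcomes, leftover


def _finish_update(
    position: np.ndarray,
    velocity: np.ndarray,
    task_mask: np.ndarray,
    fitness: float | None = None,
) -> Particle:
    """Shared tail of every loser update: Eq.-3 step, clamps, mask re-zero."""
    position = position + velocity
    velocity = np.clip(velocity, -1.0, 1.0)
    position = np.clip(position, 0.0, 1.0)
    position[~task_mask] = 0.0
    velocity[~task_mask] = 0.0
    return Particle(position, velocity, fitness)


def _draw_coeffs(
    rng: np.random.Generator, d: int, coeffs=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """r1, r2, r3 as per-dimension U[0,1] vectors, in that fixed draw order.

    ``coeffs`` is a test hook forcing the three vectors (scalars broadcast).
    """
    if coeffs is not None:
        r1, r2, r3 = (np.broadcast_to(np.asarray(c, float), (d,)) for c in coeffs)
        return r1, r2, r3
    return rng.random(d), rng.random(d), rng.random(d)


def classical_loser_update(
    loser: Particle,
    winner: Particle,
    mean_position: np.ndarray,
    phi: float,
    rng: np.random.Generator,
    task_mask: np.ndarray,
    *,
    coeffs=None,
) -> Particle:
    """Classical competitive-swarm loser update toward winner and centroid."""
    if loser.position.shape != winner.position.shape:
        raise ValueError("loser and winner have mismatched dimensionality")
    if mean_position.shape != loser.position.shape:
        raise ValueError("mean position has mismatched dimensionality")
    d = loser.position.size
    r1, r2, r3 = _draw_coeffs(rng, d, coeffs)
    v = (
        r1 * loser.velocity
        + r2 * (winner.position - loser.position)
        + phi * r3 * (mean_position - loser.position)
    )
    return _finish_update(loser.position.copy(), v, np.asarray(task_mask, bool))


def select_elites(swarm: Swarm, k_elite: int) -> ElitePool:
    """The K lowest-fitness particles (ties by index), copied, with their mean."""
    if k_elite < 1:
        raise ValueError("k_elite must be >= 1")
    fitness = swarm.fitness_values()
    if not np.all(np.isfinite(fitness)):
        raise ValueError("all particles must be evaluated before elite selection")
    k = min(k_elite, swarm.pop_size)
    order = np.lexsort((np.arange(swarm.pop_size), fitness))[:k]
    members = [swarm.particles[i].copy() for i in order]
    elite_mean = np.mean([p.position for p in members], axis=0)
    return ElitePool(members, elite_mean, k_elite)
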