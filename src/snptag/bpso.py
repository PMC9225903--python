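"""Constrained binary particle swarm optimization over the candidate set.

Particles are bit vectors over the candidate tag set SI; a 1 selects
that candidate as a tag SNP. The swarm runs in two phases:

* early phase — classic binary PSO: inertia velocity update
  ``v <- w v + c1 rand (pbest - x) + c2 Rand (gbest - x)``, sigmoid
  probability mapping ``1/(1+exp(-v))``, stochastic bit resampling;
* late phase — the inertia term is dropped so particles home in on the
  incumbent optima, and the mapping becomes ``|2/(1+exp(-v)) - 1|``
  (0 at v = 0, → 1 as |v| grows), interpreted as the probability of
  flipping toward the sign of v; v = 0 leaves the bit untouched.

After every position update, a repair step restores the exact tag
budget S: surplus bits are cleared keeping the candidates with the
largest cluster sizes, deficits are filled from the unselected
candidates with the largest cluster sizes (ties to the lower index).
Fitness is the fraction of all m loci covered by the classes of the
selected candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import EquivalenceClustering, candidate_set
from .haplotypes import HaplotypeMatrix

__all__ = [
    "SwarmConfig",
    "Particle",
    "SwarmState",
    "InfeasibleConfigError",
    "init_swarm",
    "fitness",
    "velocity_update",
    "map_probability",
    "position_update",
    "repair",
    "step",
    "run",
]


class InfeasibleConfigError(ValueError):
    """The requested tag count S exceeds the candidate set size."""


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters.

    ``switch_fraction`` splits ``max_iter`` into the early phase
    ``[0, switch_fraction * max_iter)`` and the late phase. ``S`` is the
    pregiven tag-SNP count every particle is repaired to.
    """

    S: int
    population_size: int = 30
    max_iter: int = 200
    switch_fraction: float = 0.5
    c1: float = 2.0
    c2: float = 2.0
    w: float = 1.0
    v_min: float = -4.0
    v_max: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.population_size < 1 or self.max_iter < 1:
            raise ValueError("population_size and max_iter must be positive")
        if not 0.0 < self.switch_fraction <= 1.0:
            raise ValueError("switch_fraction must lie in (0, 1]")
        if self.v_min >= self.v_max:
            raise ValueError("v_min must be < v_max")
        if self.c1 <= 0 or self.c2 <= 0 or self.w < 0:
            raise ValueError("c1, c2 must be > 0 and w >= 0")

    def phase_at(self, iteration: int) -> str:
        """'early' or 'late' for a 0-based iteration index."""
        boundary = self.switch_fraction * self.max_iter
        return "early" if iteration < boundary else "late"


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0
    fitness_history: list[float] = field(default_factory=list)


def fitness(position: np.ndarray, clus: EquivalenceClustering,
            m_total: int) -> float:
    """Fraction of all loci covered: sum of selected |clu| over m."""
    sizes = clus.candidate_class_sizes
    position = np.asarray(position)
    if position.shape[0] != sizes.shape[0]:
        raise ValueError("position length must equal the candidate count")
    return float(sizes[position.astype(bool)].sum()) / m_total


def repair(position: np.ndarray, S: int,
           clus: EquivalenceClustering) -> np.ndarray:
    """Force exactly S selected candidates, preferring large clusters.

    Surplus: among selected candidates keep the S with the largest
    cluster sizes, clear the rest. Deficit: set the missing count from
    the unselected candidates with the largest cluster sizes. Ties are
    broken toward the lower candidate index. Returns a new vector.
    """
    sizes = clus.candidate_class_sizes
    n_cand = sizes.shape[0]
    if S > n_cand:
        raise InfeasibleConfigError(
            f"S={S} exceeds candidate set size |SI|={n_cand}"
        )
    pos = np.asarray(position).astype(np.uint8).copy()
    count = int(pos.sum())
    if count == S:
        return pos
    # stable sort on -size keeps ascending index order within ties
    if count > S:
        selected = np.flatnonzero(pos)
        order = selected[np.argsort(-sizes[selected], kind="stable")]
        pos[order[S:]] = 0
    else:
        unselected = np.flatnonzero(pos == 0)
        order = unselected[np.argsort(-sizes[unselected], kind="stable")]
        pos[order[: S - count]] = 1
    return pos


def velocity_update(p: Particle, gbest: np.ndarray, cfg: SwarmConfig,
                    phase: str, rng: np.random.Generator) -> np.ndarray:
    """Early: inertia + cognitive + social; late: no inertia. Clamped."""
    x = p.position.astype(float)
    r1 = rng.random(x.shape[0])
    r2 = rng.random(x.shape[0])
    pull = (cfg.c1 * r1 * (p.pbest_position - x)
            + cfg.c2 * r2 * (gbest - x))
    if phase == "early":
        v = cfg.w * p.velocity + pull
    elif phase == "late":
        v = pull
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return np.clip(v, -cfg.v_max, cfg.v_max)


def map_probability(v, phase: str):
    """Velocity-to-probability transfer function.

    Early phase: the sigmoid ``1/(1+exp(-v))``. Late phase: 0 at v = 0
    and ``|2/(1+exp(-v)) - 1|`` otherwise — symmetric in v, increasing
    in |v|, saturating at 1 — read as the probability that the bit
    flips toward the sign of v.
    """
    v = np.asarray(v, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-v))
    if phase == "early":
        out = sig
    elif phase == "late":
        out = np.where(v < 0, 1.0 - 2.0 * sig,
                       np.where(v > 0, 2.0 * sig - 1.0, 0.0))
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return out if out.ndim else float(out)


def position_update(p: Particle, phase: str,
                    rng: np.random.Generator) -> np.ndarray:
    """Resample (early) or conditionally flip (late) each bit."""
    v = p.velocity
    prob = np.asarray(map_probability(v, phase))
    u = rng.random(v.shape[0])
    if phase == "early":
        return (prob >= u).astype(np.uint8)
    fire = prob >= u
    new = p.position.astype(np.uint8).copy()
    new[(v < 0) & fire] = 0
    new[(v > 0) & fire] = 1
    return new


def init_swarm(cfg: SwarmConfig, clus: EquivalenceClustering,
               rng: np.random.Generator) -> SwarmState:
    """Random positions repaired to S ones; velocities uniform in range."""
    n_cand = len(clus.centers)
    if cfg.S > n_cand:
        raise InfeasibleConfigError(
            f"S={cfg.S} exceeds candidate set size |SI|={n_cand}; "
            "lower lambda to enlarge the candidate set"
        )
    m_total = clus.n_loci
    particles: list[Particle] = []
    for _ in range(cfg.population_size):
        pos = repair(rng.integers(0, 2, size=n_cand), cfg.S, clus)
        vel = cfg.v_min + rng.random(n_cand) * (cfg.v_max - cfg.v_min)
        f = fitness(pos, clus, m_total)
        particles.append(Particle(pos, vel, pos.copy(), f))
    best = max(range(len(particles)),
               key=lambda i: particles[i].pbest_fitness)
    state = SwarmState(
        particles=particles,
        gbest_position=particles[best].pbest_position.copy(),
        gbest_fitness=particles[best].pbest_fitness,
    )
    state.fitness_history.append(state.gbest_fitness)
    return state


def step(state: SwarmState, cfg: SwarmConfig, clus: EquivalenceClustering,
         rng: np.random.Generator) -> SwarmState:
    """One synchronous swarm iteration; returns the mutated state.

    pbest/gbest are replaced on strict fitness improvement only, so the
    gbest fitness history is non-decreasing and the first-found optimum
    is retained on ties.
    """
    phase = cfg.phase_at(state.iteration)
    m_total = clus.n_loci
    for p in state.particles:
        p.velocity = velocity_update(p, state.gbest_position, cfg, phase, rng)
        p.position = repair(position_update(p, phase, rng), cfg.S, clus)
        f = fitness(p.position, clus, m_total)
        if f > p.pbest_fitness:
            p.pbest_fitness = f
            p.pbest_position = p.position.copy()
        if f > state.gbest_fitness:
            state.gbest_fitness = f
            state.gbest_position = p.position.copy()
    state.iteration += 1
    state.fitness_history.append(state.gbest_fitness)
    return state


def optimize(clus: EquivalenceClustering,
             cfg: SwarmConfig) -> tuple[list[int], SwarmState]:
    """Run the swarm on an existing clustering; tags as locus indices."""
    rng = np.random.default_rng(cfg.seed)
    state = init_swarm(cfg, clus, rng)
    for _ in range(cfg.max_iter):
        step(state, cfg, clus, rng)
    selected = np.flatnonzero(state.gbest_position)
    tags = sorted(clus.centers[k] for k in selected)
    return tags, state


def run(hm: HaplotypeMatrix, cfg: SwarmConfig, lam: float) -> list[int]:
    """Cluster, optimize, and decode: returns exactly S tag locus indices."""
    clus = candidate_set(hm, lam)
    tags, _ = optimize(clus, cfg)
    return tags
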