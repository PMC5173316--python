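"""Particle Swarm Optimization for embedded feature selection/weighting.

Star-topology PSO over the unit hypercube [0, 1]^d. The first block of
coordinates encodes the categorical inclusion mask (rounded at 0.5,
binary-PSO style); the remaining coordinates pass through as interval
feature weights. The fitness of a decoded transform is the F-score of a
bagged decision tree refitted under that transform and evaluated by
resubstitution on the training set (optionally out-of-bag).

Velocity update: v' = w v + c1 r1 (pbest - x) + c2 r2 (gbest - x) with
per-component U(0,1) draws, clamped to +-vmax; position update
x' = x + v' clamped to [0, 1]. The inertia decays geometrically,
w_n = w0 * damping^n, trading early exploration for late exploitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable
from .diagnostics import confusion, f_score
from .ensemble_tree import (DEFAULT_N_TREES, EncodedMatrix, FeatureTransform,
                            bagged_fit, bagged_predict, encode_cohort,
                            oob_predict)

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "update_velocity",
    "update_position",
    "decode_particle",
    "make_tree_fitness",
    "pso_maximize",
    "optimize",
]


@dataclass
class SwarmConfig:
    """Swarm hyperparameters (defaults follow the study settings)."""

    c1: float = 2.0           #: cognitive acceleration
    c2: float = 2.0           #: social acceleration
    w0: float = 1.0           #: initial inertia
    damping: float = 0.99     #: per-iteration inertia multiplier
    n_particles: int = 20
    max_iter: int = 100
    vmax: float = 4.0         #: velocity clamp
    patience: int = 20        #: early stop after this many stale iterations
    improvement_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.c1, self.c2, self.w0, self.vmax) < 0:
            raise ValueError("coefficients must be non-negative")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must lie in (0, 1]")
        if self.n_particles < 2 or self.max_iter < 1:
            raise ValueError("need >= 2 particles and >= 1 iteration")


@dataclass
class SwarmState:
    """Positions/velocities plus personal and global bests."""

    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    fitness_history: list = field(default_factory=list)
    mean_fitness_history: list = field(default_factory=list)
    iteration: int = 0

    def convergence_log(self) -> str:
        """CSV (iteration, global best, swarm mean) for convergence plots."""
        lines = ["iteration,global_best_fitness,mean_fitness"]
        for i, (g, m) in enumerate(zip(self.fitness_history,
                                       self.mean_fitness_history)):
            lines.append(f"{i},{g:.6f},{m:.6f}")
        return "\n".join(lines) + "\n"


def update_velocity(velocity, position, pbest, gbest, w: float,
                    config: SwarmConfig, rng: np.random.Generator) -> np.ndarray:
    """One inertia + cognitive + social velocity step, clamped to +-vmax."""
    velocity = np.asarray(velocity, dtype=float)
    position = np.asarray(position, dtype=float)
    r1 = rng.random(velocity.shape)
    r2 = rng.random(velocity.shape)
    v = (w * velocity
         + config.c1 * r1 * (np.asarray(pbest) - position)
         + config.c2 * r2 * (np.asarray(gbest) - position))
    return np.clip(v, -config.vmax, config.vmax)


def update_position(position, velocity) -> np.ndarray:
    """x' = x + v', clamped to the unit box."""
    return np.clip(np.asarray(position, dtype=float) + velocity, 0.0, 1.0)


def decode_particle(position, categorical_names, interval_names) -> FeatureTransform:
    """Round the categorical block at 0.5; pass interval weights through."""
    x = np.asarray(position, dtype=float)
    k = len(categorical_names)
    if len(x) != k + len(interval_names):
        raise ValueError("position dimension does not match candidates")
    mask = x[:k] >= 0.5
    weights = x[k:].copy()
    return FeatureTransform(list(categorical_names), list(interval_names),
                            mask, weights)


def make_tree_fitness(enc: EncodedMatrix, n_trees: int = DEFAULT_N_TREES,
                      bootstrap_seed: int = 0, mode: str = "resubstitution"):
    """Fitness closure: train F-score of the bag under a decoded transform.

    All calls share one bootstrap seed so particles compete on the same
    resamples. ``mode='oob'`` scores out-of-bag instead of resubstitution
    (less optimistic; off by default to keep the published objective).
    """
    if mode not in {"resubstitution", "oob"}:
        raise ValueError("mode must be 'resubstitution' or 'oob'")

    def fitness(position: np.ndarray) -> float:
        transform = decode_particle(position, enc.cat_names, enc.num_names)
        if transform.is_degenerate:
            return 0.0
        model = bagged_fit(enc, transform, n_trees=n_trees, seed=bootstrap_seed,
                           keep_oob=(mode == "oob"))
        pred = (oob_predict(model, enc) if mode == "oob"
                else bagged_predict(model, enc))
        cm = confusion(enc.y, pred)
        pr = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else 0.0
        se = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0
        return f_score(pr, se)

    return fitness


def pso_maximize(fn, dim: int, config: SwarmConfig) -> tuple:
    """Run the swarm on ``fn`` over [0,1]^dim; returns (best x, state).

    Deterministic under ``config.seed``. Stops at ``max_iter`` or when
    the global best has not improved by ``improvement_tol`` for
    ``patience`` consecutive iterations.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_particles
    x = rng.uniform(0.0, 1.0, size=(p, dim))
    v = rng.uniform(-1.0, 1.0, size=(p, dim))
    fit = np.array([fn(x[i]) for i in range(p)], dtype=float)
    pbest_x = x.copy()
    pbest_f = fit.copy()
    g = int(np.argmax(pbest_f))
    state = SwarmState(positions=x, velocities=v, pbest_positions=pbest_x,
                       pbest_fitness=pbest_f, gbest_position=pbest_x[g].copy(),
                       gbest_fitness=float(pbest_f[g]))
    state.fitness_history.append(state.gbest_fitness)
    state.mean_fitness_history.append(float(fit.mean()))

    stale = 0
    for n in range(config.max_iter):
        w = config.w0 * config.damping ** n
        for i in range(p):
            v[i] = update_velocity(v[i], x[i], pbest_x[i], state.gbest_position,
                                   w, config, rng)
            x[i] = update_position(x[i], v[i])
        fit = np.array([fn(x[i]) for i in range(p)], dtype=float)
        improved = fit > pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = fit[improved]
        g = int(np.argmax(pbest_f))
        gain = float(pbest_f[g]) - state.gbest_fitness
        if pbest_f[g] > state.gbest_fitness:
            state.gbest_fitness = float(pbest_f[g])
            state.gbest_position = pbest_x[g].copy()
        state.iteration = n + 1
        state.fitness_history.append(state.gbest_fitness)
        state.mean_fitness_history.append(float(fit.mean()))
        stale = 0 if gain > config.improvement_tol else stale + 1
        if stale >= config.patience:
            break
    return state.gbest_position.copy(), state


def optimize(train: CohortTable, categorical_candidates, interval_candidates,
             config: SwarmConfig | None = None,
             n_trees: int = DEFAULT_N_TREES,
             fitness_mode: str = "resubstitution") -> tuple:
    """Embedded feature selection on a training cohort.

    Returns the best :class:`FeatureTransform` and the final
    :class:`SwarmState`. The candidate lists come from the statistical
    filter: categorical candidates are mask bits, interval candidates
    carry real weights.
    """
    config = config or SwarmConfig()
    if not categorical_candidates and not interval_candidates:
        raise ValueError("empty candidate set")
    enc = encode_cohort(train, categorical_candidates, interval_candidates)
    rng = np.random.default_rng(config.seed)
    bootstrap_seed = int(rng.integers(0, 2**31 - 1))
    fn = make_tree_fitness(enc, n_trees=n_trees, bootstrap_seed=bootstrap_seed,
                           mode=fitness_mode)
    best_x, state = pso_maximize(fn, len(categorical_candidates) + len(interval_candidates),
                                 SwarmConfig(**{**config.__dict__, "seed": int(rng.integers(0, 2**31 - 1))}))
    transform = decode_particle(best_x, categorical_candidates, interval_candidates)
    return transform, state
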