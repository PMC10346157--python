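"""Particle swarm optimization with per-particle emotional state (IPSO).

Each particle carries a scalar emotional state eX in [-1, 1], initialised
uniformly in [-0.1, 0.1].  After every evaluation the state rises when the
particle improved and falls otherwise, by an amount scaled against the gap
between the swarm's global best gb and global worst gw fitness:

    improved:  eX += (f_prev - f) * (f - gb) / (gw - gb)^2
    worsened:  eX -= (f - f_prev) * (gw - f) / (gw - gb)^2

The swarm is then partitioned into happy / normal / sad groups around the mean
emotional state, and each group moves by a different rule:

* normal  — the classical velocity update
            V <- xi*V + c1*r1*(pBest - x) + c2*r2*(gBest - x); x <- x + V
* happy   — the same update with the cognitive and social terms scaled by
            Weber-Fechner perception coefficients r = -k*ln(S/S0), where the
            stimulus S is the absolute fitness gap to gBest (global
            perception) or pBest (historical perception)
* sad     — a restart: V <- c1_restart*(u-l)*rand[-1,1] and the position jumps
            to the previous global best (probability 1/2) or to a random point
            l + (u-l)*rand[-1,1], clamped to the box

A vanilla PSO baseline (every particle permanently "normal") shares the same
random-stream layout, so forcing the IPSO partition to all-normal reproduces
the PSO trajectory bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "SwarmConfig",
    "Particle",
    "SwarmState",
    "OptimizeResult",
    "init_swarm",
    "update_emotion",
    "partition_emotions",
    "perception",
    "step_normal",
    "step_happy",
    "step_sad",
    "ipso_optimize",
    "pso_optimize",
]

logger = logging.getLogger("fermsense.ipso")

HAPPY, NORMAL, SAD = "happy", "normal", "sad"

_PARTITION_RULES = ("mean-of-extremes", "tertiles", "all-normal")

# Perception coefficient clamp: keeps happy-particle velocity terms bounded.
_R_MIN, _R_MAX = 0.1, 2.0
_EPS = 1e-12


@dataclass(frozen=True)
class SwarmConfig:
    """Search box, swarm geometry and update constants.

    ``c1``/``c2`` are the velocity-update acceleration weights (constriction
    style defaults); ``restart_c1`` is the separate amplitude constant of the
    sad-particle restart, 0.35 by default.  ``weber_k`` and ``stimulus_floor``
    parameterize the Weber-Fechner perception law; the stimulus threshold S0
    is recomputed adaptively each iteration as 1e-3*(gw - gb) and floored at
    ``stimulus_floor``.
    """

    size: int = 100
    dims: int = 2
    lower: tuple = (0.0, 0.0)
    upper: tuple = (1.0, 1.0)
    inertia: float = 0.729
    c1: float = 1.494
    c2: float = 1.494
    restart_c1: float = 0.35
    weber_k: float = 1.0
    stimulus_floor: float = 1e-12
    max_iter: int = 200
    fitness_threshold: float | None = None
    seed: int = 0
    partition_rule: str = "mean-of-extremes"
    init_positions: tuple = ()  # fixed starting positions for the first particles

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float).ravel()
        upper = np.asarray(self.upper, dtype=float).ravel()
        if lower.shape != (self.dims,) or upper.shape != (self.dims,):
            raise ValidationError(
                f"lower/upper must have length dims={self.dims}"
            )
        if not np.all(lower < upper):
            raise ValidationError("lower must be elementwise < upper")
        if self.size < 3:
            raise ValidationError("swarm size must be >= 3")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.weber_k <= 0 or self.stimulus_floor <= 0:
            raise ValidationError("weber_k and stimulus_floor must be positive")
        if self.partition_rule not in _PARTITION_RULES:
            raise ValidationError(
                f"partition_rule must be one of {_PARTITION_RULES}"
            )
        init = tuple(tuple(float(v) for v in p) for p in self.init_positions)
        if len(init) > self.size:
            raise ValidationError("more init_positions than particles")
        for p in init:
            if len(p) != self.dims:
                raise ValidationError("init_positions entries must have length dims")
        object.__setattr__(self, "init_positions", init)
        object.__setattr__(self, "lower", tuple(lower))
        object.__setattr__(self, "upper", tuple(upper))

    @property
    def box(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lower), np.asarray(self.upper)


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    fitness: float
    pbest: np.ndarray
    pbest_fitness: float
    emotion: float = 0.0
    state: str = NORMAL


@dataclass
class SwarmState:
    particles: list
    gbest: np.ndarray
    gbest_fitness: float
    gworst_fitness: float
    iteration: int = 0


@dataclass
class OptimizeResult:
    x: np.ndarray
    fun: float
    trace: np.ndarray  # best fitness after each iteration
    n_iter: int
    n_eval: int

    def trace_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"iteration": np.arange(1, len(self.trace) + 1), "best_fitness": self.trace}
        ).to_csv(path, index=False)


def _rngs(seed: int):
    """Three independent substreams: positions, emotions, per-iteration steps.

    The emotion stream is separate so that the vanilla PSO baseline (which
    never draws emotions) consumes exactly the same position/step streams.
    """
    c_pos, c_emo, c_step = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(c_pos),
        np.random.default_rng(c_emo),
        np.random.default_rng(c_step),
    )


def init_swarm(config: SwarmConfig, objective, *, emotional: bool = True) -> SwarmState:
    """Uniform positions in the box, zero velocities, eX ~ U[-0.1, 0.1]."""
    rng_pos, rng_emo, _ = _rngs(config.seed)
    lower, upper = config.box
    positions = rng_pos.uniform(lower, upper, size=(config.size, config.dims))
    for i, p in enumerate(config.init_positions):
        positions[i] = _clamp(np.asarray(p), lower, upper)
    emotions = (
        rng_emo.uniform(-0.1, 0.1, size=config.size)
        if emotional
        else np.zeros(config.size)
    )
    particles = []
    for i in range(config.size):
        f = float(objective(positions[i]))
        if not math.isfinite(f):
            raise ValidationError(
                f"objective returned non-finite value {f} at initial point "
                f"{positions[i].tolist()}"
            )
        particles.append(
            Particle(
                position=positions[i].copy(),
                velocity=np.zeros(config.dims),
                fitness=f,
                pbest=positions[i].copy(),
                pbest_fitness=f,
                emotion=float(emotions[i]),
            )
        )
    best = min(particles, key=lambda p: p.pbest_fitness)
    worst = max(p.fitness for p in particles)
    return SwarmState(
        particles=particles,
        gbest=best.pbest.copy(),
        gbest_fitness=best.pbest_fitness,
        gworst_fitness=worst,
        iteration=0,
    )


def update_emotion(particle: Particle, prev_fitness: float, state: SwarmState) -> float:
    """New emotional state after comparing the particle's fitness with its
    previous value; the (gw - gb)^2 denominator is guarded and the result is
    clamped to [-1, 1]."""
    gb, gw = state.gbest_fitness, state.gworst_fitness
    with np.errstate(over="ignore"):
        denom = float(np.square(np.float64(gw) - np.float64(gb)))  # inf-safe
    if not math.isfinite(denom) or denom < _EPS:
        return particle.emotion
    f = particle.fitness
    with np.errstate(invalid="ignore", over="ignore"):
        if f < prev_fitness:  # improved (minimization)
            delta = (prev_fitness - f) * (f - gb) / denom
            e = particle.emotion + delta
        else:
            delta = (f - prev_fitness) * (gw - f) / denom
            e = particle.emotion - delta
    if not math.isfinite(e):
        e = particle.emotion
    return float(np.clip(e, -1.0, 1.0))


def partition_emotions(state: SwarmState, rule: str = "mean-of-extremes") -> list:
    """Label every particle happy / normal / sad from the multiset of eX.

    ``mean-of-extremes`` (default): with swarm mean m, particles whose eX is at
    or above the mean of {eX > m} are happy, those at or below the mean of
    {eX < m} are sad, the rest normal.  Location-covariant; all-equal eX
    degenerates to all-normal.  ``tertiles``: sorted thirds (low third sad,
    top third happy).  ``all-normal``: forces the vanilla PSO reduction.
    """
    e = np.array([p.emotion for p in state.particles])
    n = e.size
    if n == 0:
        return []
    labels = [NORMAL] * n
    if rule == "all-normal":
        pass
    elif rule == "tertiles":
        order = np.argsort(e, kind="stable")
        third = n // 3
        for i in order[:third]:
            labels[i] = SAD
        for i in order[n - third :]:
            labels[i] = HAPPY
    elif rule == "mean-of-extremes":
        m = e.mean()
        up, lo = e > m, e < m
        if up.any():
            thr_hi = e[up].mean()
            for i in np.nonzero(e >= thr_hi)[0]:
                labels[i] = HAPPY
        if lo.any():
            thr_lo = e[lo].mean()
            for i in np.nonzero(e <= thr_lo)[0]:
                labels[i] = SAD
    else:
        raise ValidationError(f"unknown partition rule {rule!r}")
    for p, s in zip(state.particles, labels):
        p.state = s
    return labels


def perception(
    fitness_gap: float,
    *,
    k: float = 1.0,
    s0: float = 1e-3,
    bounds: tuple | None = (_R_MIN, _R_MAX),
) -> float:
    """Weber-Fechner perception coefficient r = -k*ln(S/S0) with S = |gap|.

    Larger stimuli are perceived logarithmically more weakly.  A zero gap
    (stimulus at or below threshold) saturates at the upper clamp; pass
    ``bounds=None`` for the raw, unclamped value.
    """
    s = abs(float(fitness_gap))
    if s <= 0.0 or s0 <= 0.0:
        return bounds[1] if bounds is not None else math.inf
    r = -k * math.log(s / s0)
    if bounds is not None:
        r = min(max(r, bounds[0]), bounds[1])
    return float(r)


def _clamp(x: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(x, lower), upper)


def step_normal(particle: Particle, state: SwarmState, config: SwarmConfig, rng) -> Particle:
    lower, upper = config.box
    r1 = rng.random(config.dims)
    r2 = rng.random(config.dims)
    v = (
        config.inertia * particle.velocity
        + config.c1 * r1 * (particle.pbest - particle.position)
        + config.c2 * r2 * (state.gbest - particle.position)
    )
    particle.velocity = v
    particle.position = _clamp(particle.position + v, lower, upper)
    return particle


def adaptive_stimulus_threshold(state: SwarmState, config: SwarmConfig) -> float:
    """Per-iteration stimulus threshold S0: the swarm's median fitness gap to
    the global best, floored at ``config.stimulus_floor``.

    Placing the unit stimulus at the typical gap centres the perception
    coefficients: particles near the best perceive strongly (r -> upper
    clamp), far stragglers weakly (r -> lower clamp).
    """
    gaps = np.abs([p.fitness - state.gbest_fitness for p in state.particles])
    return max(float(np.median(gaps)), config.stimulus_floor)


def step_happy(
    particle: Particle,
    state: SwarmState,
    config: SwarmConfig,
    rng,
    *,
    s0: float | None = None,
) -> Particle:
    """Normal update with cognitive/social terms scaled by the global and
    historical perception coefficients."""
    lower, upper = config.box
    if s0 is None:
        s0 = adaptive_stimulus_threshold(state, config)
    rg = perception(state.gbest_fitness - particle.fitness, k=config.weber_k, s0=s0)
    rh = perception(particle.pbest_fitness - particle.fitness, k=config.weber_k, s0=s0)
    r1 = rng.random(config.dims)
    r2 = rng.random(config.dims)
    v = (
        config.inertia * particle.velocity
        + config.c1 * r1 * rg * (particle.pbest - particle.position)
        + config.c2 * r2 * rh * (state.gbest - particle.position)
    )
    particle.velocity = v
    particle.position = _clamp(particle.position + v, lower, upper)
    return particle


def step_sad(particle: Particle, state: SwarmState, config: SwarmConfig, rng) -> Particle:
    """Restart: uniform velocity in +-restart_c1*(u-l); position jumps to the
    previous global best (p = 1/2) or is re-initialized uniformly over the
    search box.  The particle's pbest memory is retained."""
    lower, upper = config.box
    span = upper - lower
    particle.velocity = config.restart_c1 * span * rng.uniform(-1.0, 1.0, config.dims)
    if rng.random() < 0.5:
        particle.position = state.gbest.copy()
    else:
        particle.position = lower + span * rng.random(config.dims)
    return particle


def _optimize(objective, config: SwarmConfig, *, emotional: bool) -> OptimizeResult:
    _, _, rng_step = _rngs(config.seed)
    lower, upper = config.box
    state = init_swarm(config, objective, emotional=emotional)
    n_eval = config.size
    prev_fitness = np.array([p.fitness for p in state.particles])
    first_iteration = True
    trace = []
    rule = config.partition_rule if emotional else "all-normal"

    for t in range(1, config.max_iter + 1):
        state.iteration = t
        if not first_iteration:
            # evaluate moved particles
            for i, p in enumerate(state.particles):
                f = objective(p.position)
                n_eval += 1
                if not math.isfinite(f):
                    logger.warning(
                        "non-finite objective at %s (iter %d); re-sampling particle",
                        p.position.tolist(),
                        t,
                    )
                    p.position = rng_step.uniform(lower, upper)
                    p.velocity = np.zeros(config.dims)
                    f = objective(p.position)
                    n_eval += 1
                    if not math.isfinite(f):
                        f = np.finfo(float).max  # finite sentinel
                p.fitness = float(f)
                if p.fitness < p.pbest_fitness:
                    p.pbest_fitness = p.fitness
                    p.pbest = p.position.copy()
            best = min(state.particles, key=lambda p: p.pbest_fitness)
            state.gbest = best.pbest.copy()
            state.gbest_fitness = best.pbest_fitness
            state.gworst_fitness = max(p.fitness for p in state.particles)

        trace.append(state.gbest_fitness)
        if (
            config.fitness_threshold is not None
            and state.gbest_fitness < config.fitness_threshold
        ):
            break

        if emotional and not first_iteration:
            for p, fp in zip(state.particles, prev_fitness):
                p.emotion = update_emotion(p, float(fp), state)
        prev_fitness = np.array([p.fitness for p in state.particles])

        partition_emotions(state, rule)
        gbest_prev = state.gbest.copy()  # sad-particle jump targets gb^{t-1}
        s0 = adaptive_stimulus_threshold(state, config)
        for p in state.particles:
            if p.state == HAPPY:
                step_happy(p, state, config, rng_step, s0=s0)
            elif p.state == SAD:
                saved = state.gbest
                state.gbest = gbest_prev
                step_sad(p, state, config, rng_step)
                state.gbest = saved
            else:
                step_normal(p, state, config, rng_step)
        first_iteration = False

    return OptimizeResult(
        x=state.gbest.copy(),
        fun=float(state.gbest_fitness),
        trace=np.array(trace),
        n_iter=len(trace),
        n_eval=n_eval,
    )


def ipso_optimize(objective, config: SwarmConfig) -> OptimizeResult:
    """Minimize ``objective`` over the box with the emotional swarm.

    The trace records the global best after each iteration and is
    non-increasing (gBest is an argmin memory).  Fully reproducible from
    ``config.seed``.
    """
    return _optimize(objective, config, emotional=True)


def pso_optimize(objective, config: SwarmConfig) -> OptimizeResult:
    """Vanilla PSO baseline: every particle updates by the normal rule."""
    return _optimize(objective, config, emotional=False)
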