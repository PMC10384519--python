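"""Tent-chaotic-sequence-improved Sparrow Search Algorithm (Tent-SSA).

A bounded continuous minimizer.  The sparrow search algorithm splits the
population into discoverers (producers), joiners (scroungers) and vigilantes
(scouts), updating their positions each iteration.  Three chaotic
improvements are layered on top of the canonical rules:

* population initialization by a tent-map sequence mapped through the
  carrier transform x = lb + (ub - lb) * Z, spreading individuals more
  evenly than uniform draws;
* chaotic disturbance of individuals with fitness no better than the
  population average (a tent-carrier candidate blended with the current
  position, accepted greedily);
* Gaussian mutation x * (1 + N(0,1)) of individuals better than the
  average, also accepted greedily.

Disabling all three toggles reduces the optimizer to canonical SSA.  The
global best is tracked elitistically, so the best-fitness history is
non-increasing by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SSAConfig
from .errors import ObjectiveError, ParameterError

__all__ = [
    "tent_sequence",
    "init_population",
    "gaussian_mutate",
    "ssa_step",
    "optimize",
    "Population",
    "OptimResult",
    "SSAState",
]

# tent-map fixed points and short cycles; iterates landing here are nudged
_TRAPS = (0.0, 0.25, 0.5, 0.75, 1.0)


def tent_sequence(z0: float, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate ``n`` tent-map iterates starting from ``z0`` in (0, 1).

    z <- 2z for z < 0.5, else 2(1 - z).  Iterates that land exactly on a
    fixed or periodic trap value {0, 1/4, 1/2, 3/4, 1} receive a small
    seeded uniform nudge (<= 1e-6) so the sequence never collapses.
    """
    if not 0.0 < z0 < 1.0:
        raise ParameterError(f"tent seed z0 must lie in (0, 1), got {z0}")
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = rng or np.random.default_rng(0)
    out = np.empty(n)
    z = float(z0)
    for i in range(n):
        z = 2.0 * z if z < 0.5 else 2.0 * (1.0 - z)
        if z in _TRAPS:
            z = min(max(z + rng.uniform(0.0, 1e-6), 1e-9), 1.0 - 1e-9)
        out[i] = z
    return out


@dataclass
class Population:
    """SSA candidate solutions with their fitness values."""

    positions: np.ndarray               # (N, D), inside [lb, ub]
    fitness: np.ndarray | None = None   # (N,)

    @property
    def favg(self) -> float:
        if self.fitness is None:
            raise ParameterError("population fitness not evaluated yet")
        return float(np.mean(self.fitness))


@dataclass
class SSAState:
    """Elitist best/worst trackers plus per-phase event counters."""

    xb: np.ndarray
    fg: float
    xw: np.ndarray
    fw: float
    stats: dict = field(default_factory=lambda: {"disturb_accepted": 0, "mutate_accepted": 0})


@dataclass
class OptimResult:
    """Outcome of an optimization run."""

    xb: np.ndarray
    fg: float
    xw: np.ndarray
    fw: float
    history: np.ndarray                 # best fitness after each iteration
    iterations: int
    stop_reason: str                    # "max_iter" | "accuracy"
    stats: dict = field(default_factory=dict)


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    f = np.array([float(objective(x)) for x in positions])
    bad = np.flatnonzero(~np.isfinite(f))
    if bad.size:
        raise ObjectiveError(
            f"objective returned a non-finite value for individual {bad[0]} "
            f"at position {positions[bad[0]]!r}"
        )
    return f


def _clamp(x: np.ndarray, config: SSAConfig) -> np.ndarray:
    return np.clip(x, config.lb, config.ub)


def init_population(config: SSAConfig, rng: np.random.Generator | None = None) -> Population:
    """Carrier initialization: x_d = lb_d + (ub_d - lb_d) * Z with tent Z.

    With ``tent_init`` disabled, Z is drawn uniformly instead.
    """
    rng = rng or np.random.default_rng(config.seed)
    shape = (config.n_pop, config.dim)
    if config.tent_init:
        z0 = float(rng.uniform(1e-6, 1.0 - 1e-6))
        z = tent_sequence(z0, config.n_pop * config.dim, rng).reshape(shape)
    else:
        z = rng.uniform(size=shape)
    positions = config.lb + (config.ub - config.lb) * z
    return Population(positions=_clamp(positions, config))


def gaussian_mutate(
    x: np.ndarray | float,
    draw: np.ndarray | float,
    lb=None,
    ub=None,
):
    """Gaussian mutation mutation(x) = x * (1 + N(0,1)), clamped to bounds."""
    out = np.asarray(x, dtype=float) * (1.0 + np.asarray(draw, dtype=float))
    if lb is not None or ub is not None:
        out = np.clip(out, lb, ub)
    return out if np.ndim(x) else float(out)


def ssa_step(
    population: Population,
    objective,
    iteration: int,
    config: SSAConfig,
    rng: np.random.Generator,
    state: SSAState,
) -> Population:
    """One Tent-SSA iteration (canonical role updates + chaotic phases).

    1. rank by fitness; the best ``pnum`` act as discoverers, the rest as
       joiners; apply the canonical position updates;
    2. ``snum`` randomly chosen vigilantes move toward the global best /
       away from the worst;
    3. re-evaluate fitness and the population average;
    4. individuals no better than average receive a chaotic disturbance
       (tent-carrier candidate blended 50/50 with the position), kept only
       if it improves them; the rest receive a Gaussian mutation under the
       same greedy rule;
    5. elitist best/worst trackers are updated; positions stay clamped.
    """
    n, d = population.positions.shape
    t = max(int(iteration), 1)
    if population.fitness is None:
        population.fitness = _evaluate(objective, population.positions)
    order = np.argsort(population.fitness, kind="stable")
    pos = population.positions[order].copy()
    fit = population.fitness[order].copy()

    # --- discoverers and joiners (canonical SSA rules) ---
    pnum = config.pnum
    r2 = rng.uniform()
    for i in range(pnum):
        if r2 < config.st:
            alpha = rng.uniform(1e-12, 1.0)
            pos[i] = pos[i] * np.exp(-(i + 1) / (alpha * config.max_iter))
        else:
            pos[i] = pos[i] + rng.normal(size=d)
    best_disc = pos[0].copy()
    for i in range(pnum, n):
        if i + 1 > n / 2:
            q = rng.normal(size=d)
            pos[i] = q * np.exp((state.xw - pos[i]) / (i + 1) ** 2)
        else:
            a = rng.choice((-1.0, 1.0), size=d)
            step = float(np.mean(np.abs(pos[i] - best_disc) * a))
            pos[i] = best_disc + step
    pos = _clamp(pos, config)

    # --- vigilantes ---
    watchers = rng.choice(n, size=config.snum, replace=False)
    for i in watchers:
        if fit[i] > state.fg:
            beta = rng.normal(size=d)
            pos[i] = state.xb + beta * np.abs(pos[i] - state.xb)
        else:
            k = rng.uniform(-1.0, 1.0)
            denom = (fit[i] - state.fw) + np.finfo(float).eps
            pos[i] = pos[i] + k * np.abs(pos[i] - state.xw) / denom
    pos = _clamp(pos, config)

    # --- re-evaluate, then chaotic disturbance / Gaussian mutation ---
    fit = _evaluate(objective, pos)
    favg = float(np.mean(fit))
    for i in range(n):
        if fit[i] >= favg:
            if not config.chaotic_disturbance:
                continue
            z0 = float(rng.uniform(1e-6, 1.0 - 1e-6))
            z = tent_sequence(z0, d, rng)
            cand = _clamp(0.5 * (pos[i] + (config.lb + (config.ub - config.lb) * z)), config)
        else:
            if not config.gaussian_mutation:
                continue
            cand = _clamp(gaussian_mutate(pos[i], rng.normal(size=d)), config)
        fc = float(objective(cand))
        if not np.isfinite(fc):
            raise ObjectiveError(f"objective returned a non-finite value for individual {i}")
        if fc < fit[i]:  # greedy acceptance
            key = "disturb_accepted" if fit[i] >= favg else "mutate_accepted"
            pos[i], fit[i] = cand, fc
            state.stats[key] += 1

    # --- elitist best / current worst ---
    ib = int(np.argmin(fit))
    if fit[ib] < state.fg:
        state.fg, state.xb = float(fit[ib]), pos[ib].copy()
    iw = int(np.argmax(fit))
    if fit[iw] > state.fw:
        state.fw, state.xw = float(fit[iw]), pos[iw].copy()
    return Population(positions=pos, fitness=fit)


def optimize(objective, config: SSAConfig) -> OptimResult:
    """Minimize ``objective`` over the box [lb, ub] with Tent-SSA.

    Runs up to ``max_iter`` iterations, stopping early once the elitist best
    fitness reaches the solution-accuracy threshold ``epsilon`` (disabled by
    default).  Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng)
    pop.fitness = _evaluate(objective, pop.positions)
    ib, iw = int(np.argmin(pop.fitness)), int(np.argmax(pop.fitness))
    state = SSAState(
        xb=pop.positions[ib].copy(),
        fg=float(pop.fitness[ib]),
        xw=pop.positions[iw].copy(),
        fw=float(pop.fitness[iw]),
    )
    history = []
    stop_reason = "max_iter"
    iterations = 0
    for it in range(1, config.max_iter + 1):
        pop = ssa_step(pop, objective, it, config, rng, state)
        history.append(state.fg)
        iterations = it
        if state.fg <= config.epsilon:
            stop_reason = "accuracy"
            break
    return OptimResult(
        xb=state.xb,
        fg=state.fg,
        xw=state.xw,
        fw=state.fw,
        history=np.array(history),
        iterations=iterations,
        stop_reason=stop_reason,
        stats=dict(state.stats),
    )
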