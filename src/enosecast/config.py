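"""Configuration objects for the simulator and the optimization pipeline.

Defaults encode the study conditions: apples stored at 20 degC go from fresh
to rotten over roughly 40 days; each acquisition session lasts 15 min; the
gas sensors measure within the array's specified ranges.  Trajectory shapes
follow post-harvest physiology: respiration consumes O2 and produces ethanol
and CO2 (saturating logistic trends), while ethylene shows the climacteric
burst typical of apple ripening (a peak near mid-storage).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .types import GASES, SENSOR_RANGES

VALID_SHAPES = ("logistic-rise", "logistic-fall", "climacteric-peak")


def rng_for(seed: int, *path: int) -> np.random.Generator:
    """Derive an independent generator from a master seed and an index path.

    All randomness in the package flows through this helper so any sample,
    session or optimizer run is reproducible in isolation.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(path)))


@dataclass(frozen=True)
class GasTrajectory:
    """Deterministic 40-day template of one gas plus its daily noise level.

    start/end are the template's values on day 1 and day n_days (enforced
    exactly: the logistic/bump is rescaled to hit both endpoints).  mid_day
    is the logistic midpoint or the climacteric peak day, width its time
    scale in days, and noise_sd_frac the daily additive Gaussian noise as a
    fraction of the template's range.
    """

    start: float
    end: float
    shape: str
    mid_day: float = 20.0
    width: float = 5.0
    noise_sd_frac: float = 0.02

    def __post_init__(self):
        if self.shape not in VALID_SHAPES:
            raise ConfigError(f"unknown trajectory shape {self.shape!r}; expected one of {VALID_SHAPES}")
        if self.noise_sd_frac < 0:
            raise ConfigError("noise sd must be >= 0")
        if self.width <= 0:
            raise ConfigError("trajectory width must be positive")


def _default_trajectories() -> dict[str, GasTrajectory]:
    return {
        # respiration products rise and saturate
        "ethanol": GasTrajectory(start=30.0, end=300.0, shape="logistic-rise"),
        "co2": GasTrajectory(start=400.0, end=4000.0, shape="logistic-rise"),
        # O2 is consumed; atmospheric 20.9 %Vol on day 1
        "o2": GasTrajectory(start=20.9, end=15.0, shape="logistic-fall"),
        # climacteric ethylene burst peaking mid-storage
        "ethylene": GasTrajectory(start=5.0, end=60.0, shape="climacteric-peak", mid_day=20.0, width=7.0),
    }


@dataclass(frozen=True)
class DielectricTrajectory:
    """Piecewise-linear fresh -> not-fresh -> decay progression.

    Each parameter (cs, d, er) moves from a mid-Fresh starting value through
    the Fresh-row lower edge at ``fresh_exit_day``, the Not-fresh-row lower
    edge at ``notfresh_exit_day``, down to an end value inside the Decay
    floors on the final day.  Breakpoints at half-integer days keep integer
    storage days away from label boundaries.
    """

    start: tuple[float, float, float] = (2.4, 6.6, 5.3)
    fresh_exit: tuple[float, float, float] = (2.0, 6.1, 5.0)
    notfresh_exit: tuple[float, float, float] = (1.2, 4.5, 3.5)
    end: tuple[float, float, float] = (0.9, 3.0, 3.0)
    fresh_exit_day: float = 13.5
    notfresh_exit_day: float = 27.0

    def __post_init__(self):
        if not 1 < self.fresh_exit_day < self.notfresh_exit_day:
            raise ConfigError("dielectric breakpoint days must satisfy 1 < fresh_exit < notfresh_exit")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic study.

    n_days:            storage horizon in days (>= 2)
    trajectories:      per-gas daily templates + noise
    session_duration:  seconds of within-session acquisition (default 900 = 15 min)
    sampling_rate:     session samples per second (Hz)
    tau:               first-order sensor response time constant in seconds
    session_noise_frac: session additive noise sd as a fraction of the plateau
    dielectric:        fresh -> decay dielectric progression
    seed:              master seed for every random draw
    """

    n_days: int = 40
    gases: tuple[str, ...] = GASES
    trajectories: dict[str, GasTrajectory] = field(default_factory=_default_trajectories)
    session_duration: float = 900.0
    sampling_rate: float = 1.0
    tau: float = 60.0
    session_noise_frac: float = 0.02
    dielectric: DielectricTrajectory = field(default_factory=DielectricTrajectory)
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 2:
            raise ConfigError("n_days must be >= 2")
        if self.tau <= 0:
            raise ConfigError("response time constant tau must be positive")
        if self.session_noise_frac < 0:
            raise ConfigError("session noise sd must be >= 0")
        if self.session_duration <= 0 or self.sampling_rate <= 0:
            raise ConfigError("session duration and sampling rate must be positive")
        if len(self.gases) != 4:
            raise ConfigError("exactly four gas channels are expected")
        for g in self.gases:
            if g not in self.trajectories:
                raise ConfigError(f"missing trajectory for gas {g!r}")
            lo, hi = SENSOR_RANGES[g]
            tr = self.trajectories[g]
            for v in (tr.start, tr.end):
                if not lo <= v <= hi:
                    raise ConfigError(
                        f"{g} trajectory level {v} outside measuring range [{lo}, {hi}]"
                    )

    def with_noise(self, daily_frac: float | None = None, session_frac: float | None = None) -> "SimulationConfig":
        """Copy of this config with all noise levels overridden."""
        traj = self.trajectories
        if daily_frac is not None:
            traj = {g: replace(t, noise_sd_frac=daily_frac) for g, t in traj.items()}
        return replace(
            self,
            trajectories=traj,
            session_noise_frac=self.session_noise_frac if session_frac is None else session_frac,
        )


@dataclass(frozen=True)
class SSAConfig:
    """Tent-SSA optimizer configuration.

    n_pop:    population size N
    pnum:     discoverer count (default ceil(0.2 N))
    snum:     vigilante count (default ceil(0.1 N))
    dim:      search-space dimension D
    lb, ub:   per-dimension bounds (scalars broadcast)
    max_iter: iteration budget T
    epsilon:  solution-accuracy stop threshold on the best fitness
              (disabled by default: -inf)
    st:       safety threshold ST in (0.5, 1]
    seed:     generator seed
    tent_init / chaotic_disturbance / gaussian_mutation: the three chaotic
              improvements; disabling all of them yields canonical SSA.
    """

    dim: int
    lb: float | np.ndarray = -5.0
    ub: float | np.ndarray = 5.0
    n_pop: int = 30
    pnum: int | None = None
    snum: int | None = None
    max_iter: int = 100
    epsilon: float = -np.inf
    st: float = 0.8
    seed: int = 0
    tent_init: bool = True
    chaotic_disturbance: bool = True
    gaussian_mutation: bool = True

    def __post_init__(self):
        if self.dim < 1:
            raise ConfigError("dimension must be >= 1")
        if self.n_pop < 2:
            raise ConfigError("population size must be >= 2")
        object.__setattr__(self, "lb", np.broadcast_to(np.asarray(self.lb, dtype=float), (self.dim,)).copy())
        object.__setattr__(self, "ub", np.broadcast_to(np.asarray(self.ub, dtype=float), (self.dim,)).copy())
        if np.any(self.lb >= self.ub):
            raise ConfigError("lower bounds must be strictly below upper bounds")
        if self.pnum is None:
            object.__setattr__(self, "pnum", int(np.ceil(0.2 * self.n_pop)))
        if self.snum is None:
            object.__setattr__(self, "snum", int(np.ceil(0.1 * self.n_pop)))
        if not 0 < self.pnum < self.n_pop:
            raise ConfigError("discoverer count must satisfy 0 < pnum < N")
        if not 0 < self.snum <= self.n_pop:
            raise ConfigError("vigilante count must satisfy 0 < snum <= N")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if not 0.5 < self.st <= 1.0:
            raise ConfigError("safety threshold ST must lie in (0.5, 1]")


@dataclass(frozen=True)
class ForecastRunConfig:
    """Outer Tent-SSA-BP prediction loop configuration.

    candidate_windows: window lengths x tried in order when the R^2 gate
                       fails ("adjust the input matrix"); cycled if t0 allows
    t0:                maximum outer iterations
    train_frac:        chronological train share of the window pairs
    ssa_pop/ssa_iter:  inner weight-search budget
    weight_bound:      SSA search box half-width per weight coordinate
    fine_tune_iters:   max L-BFGS iterations polishing the SSA optimum (0 disables)
    learning_rate:     gradient step size for the plain-BP baseline
    plain_epochs:      epochs for the unoptimized plain-BP baseline
    """

    candidate_windows: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    t0: int = 7
    train_frac: float = 0.8
    ssa_pop: int = 20
    ssa_iter: int = 40
    weight_bound: float = 3.0
    fine_tune_iters: int = 500
    learning_rate: float = 0.05
    plain_epochs: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.t0 < 1:
            raise ConfigError("t0 must be >= 1")
        if not self.candidate_windows or any(x < 1 for x in self.candidate_windows):
            raise ConfigError("candidate windows must be non-empty, each >= 1")
        if not 0 < self.train_frac < 1:
            raise ConfigError("train_frac must lie in (0, 1)")
        if self.weight_bound <= 0:
            raise ConfigError("weight bound must be positive")
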