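"""Synthetic electronic-nose data generator.

Emulates the statistical structure of an apple-storage study: per-sample
40-day gas trajectories at 20 degC (respiration + climacteric ethylene),
15-minute rise-to-plateau sensor sessions with additive noise, and a
deterministic fresh -> not-fresh -> decay dielectric progression used for
ground-truth labeling.

Templates are deterministic given the configuration; all noise flows from a
single master seed via split generators, so a zero-noise run is bit-identical
across seeds and any individual sample is reproducible in isolation.
"""
from __future__ import annotations

import numpy as np

from .config import SimulationConfig, rng_for
from .errors import BoundsError, ConfigError, ParameterError, RangeError
from .filtering import extract_features, lls_filter
from .types import (
    GASES,
    SENSOR_RANGES,
    DielectricMeasurement,
    FreshnessLabel,
    GasSeries,
    LabeledDataset,
    SensorSession,
)

__all__ = [
    "storage_template",
    "simulate_storage_series",
    "simulate_session",
    "simulate_dielectric",
    "label_of_day",
    "generate_dataset",
    "split_dataset",
    "mean_series",
]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def storage_template(gas: str, config: SimulationConfig) -> np.ndarray:
    """Noise-free daily template for one gas, days 1..n_days.

    Logistic shapes are rescaled so the template equals ``start`` exactly on
    day 1 and ``end`` exactly on day n_days; the climacteric shape is a
    Gaussian bump over a flat baseline, peaking at ``mid_day``.
    """
    tr = config.trajectories[gas]
    days = np.arange(1, config.n_days + 1, dtype=float)
    if tr.shape in ("logistic-rise", "logistic-fall"):
        s = _sigmoid((days - tr.mid_day) / tr.width)
        u = (s - s[0]) / (s[-1] - s[0])       # u(1)=0, u(n)=1
        template = tr.start + (tr.end - tr.start) * u
    elif tr.shape == "climacteric-peak":
        bump = np.exp(-0.5 * ((days - tr.mid_day) / tr.width) ** 2)
        template = tr.start + (tr.end - tr.start) * bump
    else:  # pragma: no cover - caught by config validation
        raise ConfigError(f"unknown trajectory shape {tr.shape!r}")
    lo, hi = SENSOR_RANGES[gas]
    return np.clip(template, lo, hi)


def simulate_storage_series(config: SimulationConfig, sample_seed: int = 0) -> GasSeries:
    """One sample's daily stable-value series for all four gases.

    Additive Gaussian noise with sd = ``noise_sd_frac`` x template range per
    gas, clipped to the sensor's measuring range.  Deterministic under
    ``(config, sample_seed)``; with zero noise the output equals the template
    exactly, independent of the seed.
    """
    rng = rng_for(config.seed, 0, int(sample_seed))
    days = np.arange(1, config.n_days + 1)
    values = {}
    for g in config.gases:
        template = storage_template(g, config)
        sd = config.trajectories[g].noise_sd_frac * float(np.ptp(template))
        noisy = template if sd == 0 else template + rng.normal(0.0, sd, size=template.shape)
        lo, hi = SENSOR_RANGES[g]
        values[g] = np.clip(noisy, lo, hi)
    return GasSeries(sample_id=f"sample_{sample_seed:03d}", days=days, values=values)


def simulate_session(
    plateau_values: dict[str, float],
    config: SimulationConfig,
    seed: int = 0,
) -> SensorSession:
    """Simulate one acquisition session as a first-order rise to plateau.

    Each channel follows c(t) = plateau * (1 - exp(-t / tau)) sampled at
    ``sampling_rate`` for ``session_duration`` seconds (900 samples under the
    defaults), plus additive Gaussian noise with sd proportional to the
    plateau, clipped to the sensor range.
    """
    for g in config.gases:
        if g not in plateau_values:
            raise ParameterError(f"missing plateau value for gas {g!r}")
        lo, hi = SENSOR_RANGES[g]
        if not lo <= plateau_values[g] <= hi:
            raise RangeError(
                f"{g} plateau {plateau_values[g]} outside measuring range [{lo}, {hi}]"
            )
    n = int(round(config.session_duration * config.sampling_rate))
    t = np.arange(n, dtype=float) / config.sampling_rate
    rng = rng_for(config.seed, 1, int(seed))
    channels = {}
    for g in config.gases:
        p = float(plateau_values[g])
        trace = p * (1.0 - np.exp(-t / config.tau))
        sd = config.session_noise_frac * abs(p)
        if sd > 0:
            trace = trace + rng.normal(0.0, sd, size=trace.shape)
        lo, hi = SENSOR_RANGES[g]
        channels[g] = np.clip(trace, lo, hi)
    return SensorSession(time=t, channels=channels)


def simulate_dielectric(day: float, config: SimulationConfig) -> DielectricMeasurement:
    """Dielectric parameters (cs, d, er) for a given storage day.

    Piecewise-linear interpolation from mid-Fresh starting values through the
    Fresh- and Not-fresh-row lower edges down to values inside the Decay
    floors, so early days label Fresh, mid days Not-fresh and late days
    Decay.  Deterministic (no noise) and non-increasing in day.
    """
    if not 1 <= day <= config.n_days:
        raise BoundsError(f"day {day} outside the simulated span [1, {config.n_days}]")
    dt = config.dielectric
    xs = [1.0, dt.fresh_exit_day, dt.notfresh_exit_day, float(config.n_days)]
    vals = []
    for i in range(3):
        ys = [dt.start[i], dt.fresh_exit[i], dt.notfresh_exit[i], dt.end[i]]
        vals.append(float(np.interp(day, xs, ys)))
    return DielectricMeasurement(cs=vals[0], d=vals[1], er=vals[2])


def label_of_day(day: float, config: SimulationConfig) -> FreshnessLabel:
    """Ground-truth freshness label of a storage day (dielectric + range rule)."""
    from .classify import label_from_dielectric

    return label_from_dielectric(simulate_dielectric(day, config))


def _stratified_days(n_samples: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Storage days for a dataset: uniform within label eras, round-robin
    across eras so every class is populated."""
    eras: dict[FreshnessLabel, list[int]] = {}
    for d in range(1, config.n_days + 1):
        eras.setdefault(label_of_day(d, config), []).append(d)
    era_days = [np.array(v) for _, v in sorted(eras.items())]
    days = np.empty(n_samples, dtype=int)
    for i in range(n_samples):
        pool = era_days[i % len(era_days)]
        days[i] = pool[rng.integers(len(pool))]
    return days


def generate_dataset(
    config: SimulationConfig,
    n_samples: int = 180,
    seed: int = 0,
    keep_series: bool = True,
    filter_window: int = 11,
) -> LabeledDataset:
    """Generate a labeled feature dataset of ``n_samples`` apples.

    Each sample: simulate its 40-day series, observe it on a stratified
    storage day, run a 15-min session at that day's concentrations, smooth
    it, extract stable values as the feature row, and label the day from the
    dielectric progression.  Deterministic under ``seed``.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    rng = rng_for(seed, 2)
    days = _stratified_days(n_samples, config, rng)
    features = np.empty((n_samples, len(config.gases)))
    labels: list[FreshnessLabel] = []
    series_list: list[GasSeries] = []
    for i, day in enumerate(days):
        series = simulate_storage_series(config, sample_seed=1000 * seed + i)
        series.sample_id = f"sample_{i:03d}"
        plateau = {g: float(series.values[g][day - 1]) for g in config.gases}
        session = simulate_session(plateau, config, seed=1000 * seed + i)
        smoothed = SensorSession(
            time=session.time,
            channels={g: lls_filter(v, filter_window) for g, v in session.channels.items()},
        )
        fv = extract_features(smoothed)
        features[i] = fv.stable_array(config.gases)
        labels.append(label_of_day(day, config))
        series_list.append(series)
    day_labels = [label_of_day(d, config) for d in range(1, config.n_days + 1)]
    return LabeledDataset(
        features=features,
        labels=labels,
        days=days,
        series=series_list if keep_series else None,
        day_labels=day_labels,
    )


def split_dataset(
    dataset: LabeledDataset, train_frac: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Shuffled train/test split (default 8:2, so 180 samples -> 144/36)."""
    if not 0 < train_frac < 1:
        raise ParameterError("train_frac must lie in (0, 1)")
    perm = rng_for(seed, 9).permutation(len(dataset))
    n_train = int(round(train_frac * len(dataset)))
    return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])


def mean_series(dataset: LabeledDataset, config: SimulationConfig, sample_id: str = "mean") -> GasSeries:
    """Average the stored per-sample series — a denoised training trajectory
    for fitting the forecaster."""
    if dataset.series is None:
        raise ParameterError("dataset was generated without keep_series=True")
    days = dataset.series[0].days
    values = {
        g: np.mean([s.values[g] for s in dataset.series], axis=0) for g in config.gases
    }
    return GasSeries(sample_id=sample_id, days=days, values=values)
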