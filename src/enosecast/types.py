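"""Core containers shared across the package.

The sensor array measures four gases; their order is fixed everywhere
(feature vectors, CSV columns, network inputs):

    ethanol (ppm), carbon dioxide (ppm), oxygen (%Vol), ethylene (ppm)

``SENSOR_RANGES`` holds each sensor's measuring range; all simulated and
accepted concentrations are confined to these intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

#: Canonical gas channel order (ethanol, CO2, O2, ethylene).
GASES: tuple[str, ...] = ("ethanol", "co2", "o2", "ethylene")

#: Measuring range of each sensor in native units (ppm / %Vol).
SENSOR_RANGES: dict[str, tuple[float, float]] = {
    "ethanol": (25.0, 500.0),   # MQ3
    "co2": (0.0, 10_000.0),     # MG811
    "o2": (0.0, 25.0),          # ME2-O2
    "ethylene": (0.0, 100.0),   # ME3-C2H4
}

#: CSV column name per gas (shared session/series dialect).
GAS_COLUMNS: dict[str, str] = {
    "ethanol": "ethanol_ppm",
    "co2": "co2_ppm",
    "o2": "o2_pct",
    "ethylene": "ethylene_ppm",
}


class FreshnessLabel(IntEnum):
    """Three-way freshness grade with its one-hot target encoding.

    Fresh -> [1,0,0], NotFresh -> [0,1,0], Decay -> [0,0,1].  The integer
    value orders the grades from freshest to most spoiled, which is the
    order used for tie-breaking and monotonicity checks.
    """

    FRESH = 0
    NOT_FRESH = 1
    DECAY = 2

    @property
    def one_hot(self) -> np.ndarray:
        v = np.zeros(3)
        v[int(self)] = 1.0
        return v

    @classmethod
    def from_one_hot(cls, v) -> "FreshnessLabel":
        v = np.asarray(v, dtype=float)
        if v.shape != (3,) or not np.isclose(v.sum(), 1.0) or set(np.round(v, 12)) - {0.0, 1.0}:
            raise ValueError(f"not a one-hot vector of length 3: {v!r}")
        return cls(int(np.argmax(v)))

    @property
    def csv_name(self) -> str:
        return {0: "fresh", 1: "not_fresh", 2: "decay"}[int(self)]

    @classmethod
    def from_csv_name(cls, name: str) -> "FreshnessLabel":
        table = {"fresh": 0, "not_fresh": 1, "decay": 2}
        if name not in table:
            raise ValueError(f"unknown label {name!r}")
        return cls(table[name])


@dataclass(frozen=True)
class DielectricMeasurement:
    """LCR-meter dielectric parameters used for ground-truth labeling.

    cs: equivalent capacitance in units of 1e-10 F
    d:  loss factor in units of 1e-2
    er: relative dielectric constant in units of 1e-1
    """

    cs: float
    d: float
    er: float

    def __post_init__(self):
        for name in ("cs", "d", "er"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"dielectric parameter {name} must be positive and finite, got {v}")


@dataclass
class SensorSession:
    """One ~15 min acquisition: four concentration traces on a shared clock."""

    time: np.ndarray                    # seconds, strictly increasing
    channels: dict[str, np.ndarray]     # gas name -> trace in native units

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) == 0:
            raise ValueError("time must be a non-empty 1-D array")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        self.channels = {g: np.asarray(v, dtype=float) for g, v in self.channels.items()}
        for g, v in self.channels.items():
            if v.shape != self.time.shape:
                raise ValueError(f"channel {g!r} length {len(v)} != time length {len(self.time)}")

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass
class GasSeries:
    """One sample's daily feature values for each gas over the storage horizon."""

    sample_id: str
    days: np.ndarray                    # 1-based day index
    values: dict[str, np.ndarray]       # gas name -> daily stable values

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.values = {g: np.asarray(v, dtype=float) for g, v in self.values.items()}
        for g, v in self.values.items():
            if v.shape != self.days.shape:
                raise ValueError(f"gas {g!r} length mismatch with days")

    @property
    def n_days(self) -> int:
        return len(self.days)


@dataclass
class FeatureVector:
    """Per-channel characteristic values: stable, average and maximum."""

    stable: dict[str, float]
    mean: dict[str, float]
    max: dict[str, float]

    def stable_array(self, gases=GASES) -> np.ndarray:
        return np.array([self.stable[g] for g in gases])


@dataclass
class LabeledDataset:
    """Feature rows (one stable value per gas) with freshness labels.

    ``days`` holds the storage day each sample was observed on, ``series``
    optionally the full simulated trajectory of each sample (needed for
    horizon forecasting), and ``day_labels`` the ground-truth label of every
    storage day (a pure function of day because the dielectric trajectory is
    deterministic).
    """

    features: np.ndarray                      # (n, 4) stable values, GASES order
    labels: list[FreshnessLabel]
    days: np.ndarray                          # (n,) storage day per sample
    series: list[GasSeries] | None = None
    day_labels: list[FreshnessLabel] | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.days = np.asarray(self.days, dtype=int)
        n = self.features.shape[0]
        if len(self.labels) != n or len(self.days) != n:
            raise ValueError("label/day count must equal feature row count")
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i:03d}" for i in range(n)]

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        return LabeledDataset(
            features=self.features[idx],
            labels=[self.labels[i] for i in idx],
            days=self.days[idx],
            series=None if self.series is None else [self.series[i] for i in idx],
            day_labels=self.day_labels,
            sample_ids=[self.sample_ids[i] for i in idx],
        )
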