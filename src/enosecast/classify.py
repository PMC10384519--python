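"""Freshness classification: dielectric labeling, the 4-9-3 BP classifier,
the argmax decision rule and horizon-accuracy evaluation.

Ground-truth grades come from LCR-meter dielectric ranges (equivalent
capacitance, loss factor, relative dielectric constant).  The classifier is
a 4-9-3 network — four stable gas features in, hidden width from the
Kolmogorov rule 2n+1, three one-hot freshness outputs — trained by gradient
descent; the predicted grade is the argmax of the three outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, DegenerateLabelError, EnosecastError, ParameterError
from .filtering import minmax_scale
from .network import NetworkParams, NetworkTopology, forward, train_gd
from .types import GASES, DielectricMeasurement, FreshnessLabel, LabeledDataset

__all__ = [
    "kolmogorov_hidden",
    "label_from_dielectric",
    "decide",
    "ClassifierModel",
    "train_classifier",
    "predict",
    "evaluate_horizon",
    "HorizonAccuracy",
    "DIELECTRIC_ROWS",
]

#: (Fresh, Not-fresh) closed ranges per dielectric parameter (cs, d, er).
#: The Decay row is open-ended (> 0.8 / > 2.8 / > 2.8) and overlaps the
#: others, so it acts as the fall-through class.
DIELECTRIC_ROWS: dict[FreshnessLabel, tuple[tuple[float, float], ...]] = {
    FreshnessLabel.FRESH: ((2.0, 2.5), (6.1, 6.8), (5.0, 5.5)),
    FreshnessLabel.NOT_FRESH: ((1.2, 2.0), (4.5, 5.8), (3.5, 5.0)),
}


def kolmogorov_hidden(n_in: int) -> int:
    """Hidden-layer width by the Kolmogorov rule: 2 * n_in + 1."""
    if n_in < 1:
        raise ParameterError("n_in must be >= 1")
    return 2 * n_in + 1


def _param_vote(value: float, index: int) -> FreshnessLabel:
    for label in (FreshnessLabel.FRESH, FreshnessLabel.NOT_FRESH):
        lo, hi = DIELECTRIC_ROWS[label][index]
        if lo <= value <= hi:
            return label
    return FreshnessLabel.DECAY


def label_from_dielectric(m: DielectricMeasurement) -> FreshnessLabel:
    """Majority vote of the three dielectric parameters.

    Each parameter is tested against the Fresh row first, then Not-fresh;
    anything outside both is a Decay vote (row precedence makes the
    overlapping Decay row the fall-through class).  Ties go to the
    less-fresh class.
    """
    votes = [_param_vote(v, i) for i, v in enumerate((m.cs, m.d, m.er))]
    counts = np.bincount([int(v) for v in votes], minlength=3)
    winners = np.flatnonzero(counts == counts.max())
    return FreshnessLabel(int(winners.max()))  # tie -> less fresh


def decide(outputs) -> FreshnessLabel:
    """Argmax decision over the three network outputs (ties -> fresher class)."""
    v = np.asarray(outputs, dtype=float).ravel()
    if v.shape != (3,):
        raise ParameterError(f"expected 3 output values, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ParameterError(f"non-finite classifier outputs: {v!r}")
    return FreshnessLabel(int(np.argmax(v)))


@dataclass
class ClassifierModel:
    """Trained freshness classifier with its feature normalization."""

    params: NetworkParams
    feature_lo: np.ndarray     # per-feature training minima
    feature_hi: np.ndarray     # per-feature training maxima
    gases: tuple[str, ...] = GASES
    train_accuracy: float = float("nan")

    @property
    def topology(self) -> NetworkTopology:
        return self.params.topology

    def scale(self, features: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(features, dtype=float))
        return (f - self.feature_lo) / (self.feature_hi - self.feature_lo)


def train_classifier(
    dataset: LabeledDataset,
    seed: int = 0,
    learning_rate: float = 0.1,
    epochs: int = 3000,
) -> ClassifierModel:
    """Train the 4-9-3 classifier on one-hot targets by gradient descent.

    Features are min-max normalized with bounds from the training set only.
    """
    labels = set(int(l) for l in dataset.labels)
    if len(labels) < 2:
        raise DegenerateLabelError(
            "training data contains a single class; cannot fit a classifier"
        )
    x = dataset.features
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    flat = hi <= lo
    hi = np.where(flat, lo + 1.0, hi)
    xn = (x - lo) / (hi - lo)
    y = np.stack([l.one_hot for l in dataset.labels])
    n_in = x.shape[1]
    topo = NetworkTopology(n_in, kolmogorov_hidden(n_in), 3)
    params, _ = train_gd(
        xn, y, topology=topo, learning_rate=learning_rate, epochs=epochs, seed=seed
    )
    model = ClassifierModel(params=params, feature_lo=lo, feature_hi=hi)
    preds = predict(model, x)
    model.train_accuracy = float(
        np.mean([p == t for p, t in zip(preds, dataset.labels)])
    )
    return model


def predict(model: ClassifierModel, features) -> list[FreshnessLabel]:
    """Classify feature rows (native units) with the argmax rule."""
    outputs = forward(model.params, model.scale(features))
    return [decide(row) for row in np.atleast_2d(outputs)]


@dataclass
class HorizonAccuracy:
    """Per-horizon accuracy report (one row per requested horizon)."""

    rows: list[dict] = field(default_factory=list)

    def accuracy(self, horizon: int) -> float:
        for r in self.rows:
            if r["horizon_day"] == horizon:
                return r["accuracy"]
        raise KeyError(horizon)


def evaluate_horizon(
    forecast_model,
    classifier: ClassifierModel,
    dataset: LabeledDataset,
    horizon_days,
    history_smooth_window: int | None = 5,
) -> HorizonAccuracy:
    """Accuracy of forecast-then-classify at each prediction horizon.

    For every test sample observed on storage day d, the gas concentrations
    are recursively forecast ``h`` days ahead from the sample's own history,
    the forecasted feature vector is classified, and the decision is
    compared with the ground-truth label of day d + h.  Samples whose future
    day falls beyond the simulated span (or whose history is shorter than
    the forecaster's window) are excluded from that horizon's count n.

    The observed daily history is denoised with a causal trailing linear
    least-squares fit (``history_smooth_window``; None disables) before
    seeding the rollout, so day-to-day feature noise in the last observed
    window does not propagate through the recursion.
    """
    from .filtering import trailing_linear_smooth
    from .forecast import forecast as _forecast  # local import avoids a cycle
    from .types import GasSeries

    if dataset.series is None or dataset.day_labels is None:
        raise ParameterError("dataset must carry per-sample series and day labels")
    n_days = len(dataset.day_labels)
    report = HorizonAccuracy()
    for h in horizon_days:
        if h < 0:
            raise ParameterError("horizon must be >= 0")
        if h >= n_days:
            raise BoundsError(
                f"horizon {h} reaches beyond the simulated span of {n_days} days"
            )
        hits, n_eval = 0, 0
        for i in range(len(dataset)):
            d = int(dataset.days[i])
            target_day = d + h
            if target_day > n_days:
                continue
            series = dataset.series[i]
            if h == 0:
                feats = dataset.features[i]
            else:
                if d < forecast_model.x:
                    continue
                if history_smooth_window:
                    vals = {
                        g: trailing_linear_smooth(v[:d], history_smooth_window)
                        for g, v in series.values.items()
                    }
                else:
                    vals = {g: v[:d].copy() for g, v in series.values.items()}
                hist = GasSeries(
                    sample_id=series.sample_id,
                    days=series.days[:d],
                    values=vals,
                )
                preds = _forecast(forecast_model, hist, h)
                feats = np.array([preds[g][-1] for g in classifier.gases])
            decision = predict(classifier, feats)[0]
            truth = dataset.day_labels[target_day - 1]
            hits += int(decision == truth)
            n_eval += 1
        report.rows.append(
            {
                "horizon_day": int(h),
                "n": n_eval,
                "accuracy": hits / n_eval if n_eval else float("nan"),
            }
        )
    return report
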