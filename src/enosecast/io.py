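"""CSV/JSON readers and writers for the package's interchange dialects.

All tabular artifacts are RFC-4180 CSV with a header row, UTF-8, '.'
decimal.  Floats are written with ``repr`` precision so write -> read
roundtrips are exact.  Models persist as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierModel
from .errors import EmptySessionError, SchemaError
from .forecast import ForecastModel, GasModel
from .network import NetworkParams
from .types import GAS_COLUMNS, GASES, FeatureVector, GasSeries, SensorSession

SESSION_HEADER = ["time_s"] + [GAS_COLUMNS[g] for g in GASES]
SERIES_HEADER = ["day"] + [GAS_COLUMNS[g] for g in GASES]
LABELS_HEADER = ["sample_id", "day", "label"]
FEATURES_HEADER = ["sample_id", "gas", "stable", "mean", "max"]


def _check_header(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise SchemaError(
            f"{path}: unexpected header {list(df.columns)}; expected {expected}"
        )


#: shortest-exact float formatting so write -> read roundtrips are bitwise
_FLOAT_FMT = "%.17g"


def write_session_csv(session: SensorSession, path) -> None:
    df = pd.DataFrame({"time_s": session.time})
    for g in GASES:
        df[GAS_COLUMNS[g]] = session.channels[g]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_session_csv(path) -> SensorSession:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, SESSION_HEADER, path)
    if len(df) == 0:
        raise EmptySessionError(f"{path}: no samples in session file")
    return SensorSession(
        time=df["time_s"].to_numpy(),
        channels={g: df[GAS_COLUMNS[g]].to_numpy() for g in GASES},
    )


def write_series_csv(series: GasSeries, path) -> None:
    df = pd.DataFrame({"day": series.days})
    for g in GASES:
        df[GAS_COLUMNS[g]] = series.values[g]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series_csv(path, sample_id: str | None = None) -> GasSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, SERIES_HEADER, path)
    if len(df) == 0:
        raise EmptySessionError(f"{path}: no rows in series file")
    return GasSeries(
        sample_id=sample_id or Path(path).stem,
        days=df["day"].to_numpy(),
        values={g: df[GAS_COLUMNS[g]].to_numpy() for g in GASES},
    )


def write_labels_csv(rows, path) -> None:
    """rows: iterable of (sample_id, day, FreshnessLabel)."""
    df = pd.DataFrame(
        [(sid, int(day), lab.csv_name) for sid, day, lab in rows],
        columns=LABELS_HEADER,
    )
    df.to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, LABELS_HEADER, path)
    return df


def write_features_csv(features: dict[str, FeatureVector], path) -> None:
    rows = []
    for sid, fv in features.items():
        for g in GASES:
            rows.append((sid, g, fv.stable[g], fv.mean[g], fv.max[g]))
    pd.DataFrame(rows, columns=FEATURES_HEADER).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_forecast_csv(predictions: dict[str, np.ndarray], start_day: int, path) -> None:
    rows = []
    for g in GASES:
        for i, v in enumerate(predictions[g]):
            rows.append((start_day + i, g, v))
    pd.DataFrame(rows, columns=["day", "gas", "predicted_value"]).to_csv(path, index=False)


def write_history_csv(history, path) -> None:
    pd.DataFrame(
        {"iteration": np.arange(1, len(history) + 1), "best_fitness": history}
    ).to_csv(path, index=False)


# --- model persistence -----------------------------------------------------

def _params_to_json(p: NetworkParams) -> dict:
    return {
        "w1": p.w1.tolist(),
        "b1": p.b1.tolist(),
        "w2": p.w2.tolist(),
        "b2": p.b2.tolist(),
    }


def _params_from_json(d: dict) -> NetworkParams:
    return NetworkParams(
        np.array(d["w1"]), np.array(d["b1"]), np.array(d["w2"]), np.array(d["b2"])
    )


def save_forecast_model(model: ForecastModel, path) -> None:
    payload = {
        "kind": "forecast",
        "x": model.x,
        "eps": model.eps,
        "eps0": model.eps0,
        "gate_status": model.gate_status,
        "seed": model.seed,
        "models": {
            g: {
                "x": gm.x,
                "lo": gm.lo,
                "hi": gm.hi,
                "eps": gm.eps,
                "train_mse": gm.train_mse,
                "eval_mse": gm.eval_mse,
                "params": _params_to_json(gm.params),
            }
            for g, gm in model.models.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_forecast_model(path) -> ForecastModel:
    d = json.loads(Path(path).read_text())
    if d.get("kind") != "forecast":
        raise SchemaError(f"{path}: not a forecast model file")
    models = {
        g: GasModel(
            gas=g,
            params=_params_from_json(gd["params"]),
            x=gd["x"],
            lo=gd["lo"],
            hi=gd["hi"],
            eps=gd["eps"],
            train_mse=gd["train_mse"],
            eval_mse=gd["eval_mse"],
        )
        for g, gd in d["models"].items()
    }
    return ForecastModel(
        models=models,
        x=d["x"],
        eps=d["eps"],
        eps0=d["eps0"],
        gate_status=d["gate_status"],
        seed=d["seed"],
    )


def save_classifier_model(model: ClassifierModel, path) -> None:
    payload = {
        "kind": "classifier",
        "gases": list(model.gases),
        "feature_lo": model.feature_lo.tolist(),
        "feature_hi": model.feature_hi.tolist(),
        "train_accuracy": model.train_accuracy,
        "params": _params_to_json(model.params),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_classifier_model(path) -> ClassifierModel:
    d = json.loads(Path(path).read_text())
    if d.get("kind") != "classifier":
        raise SchemaError(f"{path}: not a classifier model file")
    return ClassifierModel(
        params=_params_from_json(d["params"]),
        feature_lo=np.array(d["feature_lo"]),
        feature_hi=np.array(d["feature_hi"]),
        gases=tuple(d["gases"]),
        train_accuracy=d["train_accuracy"],
    )
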