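"""Sliding-window gas-concentration forecasting with Tent-SSA-optimized BP.

Per gas, the daily stable-value series is turned into (window -> next day)
pairs, min-max normalized with bounds taken from the training span only.
The network weights are found by Tent-SSA minimizing the training MSE of
the decoded network, then polished by a short gradient-descent fine-tune.
Model quality epsilon is the coefficient of determination R^2 on the
chronologically held-out pairs; it must exceed the gate threshold
epsilon0(x), an 8th-degree polynomial in the window length x fitted to the
empirical relationship between achievable R^2 and the input-matrix
structure.  When the gate fails, the input matrix is adjusted (the next
candidate window length) until it passes or the outer iteration budget T0
is exhausted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.optimize import minimize

from .config import ForecastRunConfig, SSAConfig, rng_for
from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    ParameterError,
)
from .filtering import minmax_scale, minmax_unscale
from .network import (
    NetworkParams,
    NetworkTopology,
    forward,
    gradients,
    mse_loss,
    params_to_vector,
    train_gd,
    vector_to_params,
)
from .ssa import optimize
from .types import GASES, SENSOR_RANGES, GasSeries
from .classify import kolmogorov_hidden

__all__ = [
    "epsilon0",
    "r_squared",
    "build_windows",
    "WindowDataset",
    "GasModel",
    "ForecastModel",
    "fit_forecaster",
    "forecast",
    "compare_optimized",
    "OptimizationReport",
]

#: epsilon0 polynomial coefficients, highest degree (x^8) first.
EPSILON0_COEFFS: tuple[float, ...] = (
    1.396e-6,
    -2.548e-5,
    -0.0003126,
    0.01221,
    -0.1327,
    0.701,
    -1.905,
    2.461,
    -0.2368,
)


def epsilon0(x: int) -> float:
    """Gate threshold epsilon0(x) for window length x (Horner evaluation).

    The raw polynomial is the gate: values are not clamped to [0, 1].
    """
    if x < 0:
        raise ParameterError(f"window length must be >= 0, got {x}")
    acc = 0.0
    for c in EPSILON0_COEFFS:
        acc = acc * x + c
    return acc


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination R^2 = 1 - SSres / SStot.

    SSres = sum (y_i - f_i)^2, SStot = sum (y_i - ybar)^2.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    f = np.asarray(y_pred, dtype=float).ravel()
    if len(y) == 0 or len(y) != len(f):
        raise ParameterError("y_true and y_pred must be equal-length and non-empty")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateVarianceError("targets have zero variance; R^2 undefined")
    ss_res = float(np.sum((y - f) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class WindowDataset:
    """Sliding-window supervised pairs built from one gas series."""

    x: int
    inputs: np.ndarray   # (n_pairs, x)
    targets: np.ndarray  # (n_pairs,)

    @property
    def n_pairs(self) -> int:
        return self.inputs.shape[0]


def build_windows(values, x: int, bounds: tuple[float, float] | None = None) -> WindowDataset:
    """Sliding windows of length ``x`` with next-day targets, in order.

    ``bounds`` (lo, hi) min-max normalizes both inputs and targets; bounds
    must come from the training span only.
    """
    v = np.asarray(values, dtype=float).ravel()
    if x < 1:
        raise ParameterError("window length must be >= 1")
    if len(v) <= x:
        raise InsufficientDataError(
            f"series length {len(v)} must exceed window length {x}"
        )
    if bounds is not None:
        v = minmax_scale(v, *bounds)
    n = len(v) - x
    inputs = np.lib.stride_tricks.sliding_window_view(v, x)[:n].copy()
    targets = v[x:].copy()
    return WindowDataset(x=x, inputs=inputs, targets=targets)


@dataclass
class GasModel:
    """Trained per-gas forecaster: network + window + normalization + R^2."""

    gas: str
    params: NetworkParams
    x: int
    lo: float
    hi: float
    eps: float           # held-out R^2
    train_mse: float
    eval_mse: float


@dataclass
class ForecastModel:
    """Four per-gas networks sharing a window length plus the gate verdict."""

    models: dict[str, GasModel]
    x: int
    eps: float                 # mean held-out R^2 across gases
    eps0: float                # gate threshold epsilon0(x)
    gate_status: str           # "passed" | "max_iterations"
    seed: int = 0

    def __post_init__(self):
        if self.gate_status == "passed" and not self.eps > self.eps0:
            raise ParameterError("gate status 'passed' requires eps > eps0")


def _polish(
    params: NetworkParams,
    topo: NetworkTopology,
    xtr: np.ndarray,
    ytr: np.ndarray,
    max_iter: int,
) -> NetworkParams:
    """Deterministic quasi-Newton polish of the SSA solution.

    Full-batch gradient descent needs ~1e5 epochs to drive the training MSE
    low enough for the R^2 gate on saturating series, so the assignment of
    the SSA optimum to the network is followed by L-BFGS on the same MSE
    with the package's analytic gradients.
    """

    def fun(v):
        p = vector_to_params(v, topo)
        return mse_loss(p, xtr, ytr), params_to_vector(gradients(p, xtr, ytr))

    res = minimize(
        fun,
        params_to_vector(params),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-16, "gtol": 1e-12},
    )
    return vector_to_params(res.x, topo)


def _split_chrono(n_pairs: int, train_frac: float) -> int:
    n_train = int(np.floor(train_frac * n_pairs))
    return min(max(n_train, 1), n_pairs - 1)


def _fit_gas(
    values: np.ndarray,
    gas: str,
    x: int,
    run_config: ForecastRunConfig,
    seed: int,
    optimizer: str,
) -> GasModel:
    raw = build_windows(values, x)
    n_train = _split_chrono(raw.n_pairs, run_config.train_frac)
    # normalization bounds from the training span only (days 1 .. x+n_train)
    train_span = values[: x + n_train]
    lo, hi = float(np.min(train_span)), float(np.max(train_span))
    if hi <= lo:  # constant training span; widen symmetrically
        lo, hi = lo - 0.5, hi + 0.5
    win = build_windows(values, x, bounds=(lo, hi))
    xtr, ytr = win.inputs[:n_train], win.targets[:n_train]
    xev, yev = win.inputs[n_train:], win.targets[n_train:]

    topo = NetworkTopology(x, kolmogorov_hidden(x), 1)
    if optimizer == "tent-ssa":
        def objective(v):
            return mse_loss(vector_to_params(v, topo), xtr, ytr[:, None])

        ssa_cfg = SSAConfig(
            dim=topo.n_params,
            lb=-run_config.weight_bound,
            ub=run_config.weight_bound,
            n_pop=run_config.ssa_pop,
            max_iter=run_config.ssa_iter,
            seed=seed,
        )
        result = optimize(objective, ssa_cfg)
        params = vector_to_params(result.xb, topo)
        if run_config.fine_tune_iters > 0:
            params = _polish(params, topo, xtr, ytr[:, None], run_config.fine_tune_iters)
    elif optimizer == "gd":
        params, _ = train_gd(
            xtr,
            ytr[:, None],
            topology=topo,
            learning_rate=run_config.learning_rate,
            epochs=run_config.plain_epochs,
            seed=seed,
        )
    else:
        raise ParameterError(f"unknown optimizer {optimizer!r}")

    pred_ev = forward(params, xev)[:, 0]
    eps = r_squared(yev, pred_ev)
    return GasModel(
        gas=gas,
        params=params,
        x=x,
        lo=lo,
        hi=hi,
        eps=eps,
        train_mse=mse_loss(params, xtr, ytr[:, None]),
        eval_mse=float(np.mean((pred_ev - yev) ** 2)),
    )


def fit_forecaster(
    series: GasSeries,
    run_config: ForecastRunConfig | None = None,
    optimizer: str = "tent-ssa",
) -> ForecastModel:
    """Fit per-gas forecasters, iterating the input-matrix structure.

    Candidate window lengths are tried in order (cycling while the outer
    budget T0 allows).  For each candidate, every gas gets its own network;
    the model's epsilon is the mean held-out R^2 across gases.  The loop
    ends as soon as epsilon exceeds the gate epsilon0(x); otherwise the best
    candidate seen is returned with gate status "max_iterations".
    """
    run_config = run_config or ForecastRunConfig()
    gases = list(series.values)
    feasible = [x for x in run_config.candidate_windows if series.n_days > x + 1]
    if not feasible:
        raise InsufficientDataError(
            f"series of {series.n_days} days is too short for every candidate "
            f"window in {run_config.candidate_windows}"
        )
    best: ForecastModel | None = None
    for outer in range(run_config.t0):
        x = feasible[outer % len(feasible)]
        sub_seed = int(rng_for(run_config.seed, 3, outer).integers(2**31))
        models = {
            g: _fit_gas(series.values[g], g, x, run_config, sub_seed, optimizer)
            for g in gases
        }
        eps = float(np.mean([m.eps for m in models.values()]))
        e0 = epsilon0(x)
        candidate = ForecastModel(
            models=models,
            x=x,
            eps=eps,
            eps0=e0,
            gate_status="passed" if eps > e0 else "max_iterations",
            seed=run_config.seed,
        )
        if best is None or candidate.eps > best.eps:
            best = candidate
        if eps > e0:
            return candidate
    return best


def forecast(model: ForecastModel, series: GasSeries, horizon: int) -> dict[str, np.ndarray]:
    """Recursive one-step-ahead forecasts, ``horizon`` days past the series end.

    Each prediction is appended to the rolling window to predict the next
    day.  Outputs are denormalized to native units and clipped to the
    sensor's measuring range.
    """
    if horizon < 0:
        raise ParameterError("horizon must be >= 0")
    out: dict[str, np.ndarray] = {}
    for gas, gm in model.models.items():
        v = series.values[gas]
        if len(v) < gm.x:
            raise InsufficientDataError(
                f"series for {gas!r} has {len(v)} days; window needs {gm.x}"
            )
        window = list(minmax_scale(v[-gm.x:], gm.lo, gm.hi))
        preds = np.empty(horizon)
        for h in range(horizon):
            nxt = float(forward(gm.params, np.asarray(window))[0])
            preds[h] = nxt
            window = window[1:] + [nxt]
        native = minmax_unscale(preds, gm.lo, gm.hi)
        lo, hi = SENSOR_RANGES.get(gas, (-np.inf, np.inf))
        out[gas] = np.clip(native, lo, hi)
    return out


@dataclass
class OptimizationReport:
    """Paired comparison of the plain-BP and Tent-SSA-BP forecasters."""

    rows: list[dict] = field(default_factory=list)

    def as_table(self) -> list[tuple[str, float, float]]:
        return [(r["variant"], r["eps"], r["eval_mse"]) for r in self.rows]


def compare_optimized(series: GasSeries, run_config: ForecastRunConfig | None = None) -> OptimizationReport:
    """Train both variants on identical data and seeds; report epsilon and MSE.

    The plain variant trains the same networks on the same window pairs by
    gradient descent from a random init; the optimized variant uses Tent-SSA
    plus fine-tuning.  MSE is on the normalized scale, averaged over gases.
    """
    run_config = run_config or ForecastRunConfig()
    report = OptimizationReport()
    for variant, optimizer in (("plain-bp", "gd"), ("tent-ssa-bp", "tent-ssa")):
        model = fit_forecaster(series, run_config, optimizer=optimizer)
        report.rows.append(
            {
                "variant": variant,
                "eps": model.eps,
                "eval_mse": float(np.mean([m.eval_mse for m in model.models.values()])),
                "x": model.x,
                "gate_status": model.gate_status,
            }
        )
    return report
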