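"""Forecaster: windows, the epsilon0 gate, R^2, fitting and recursive rollout."""
import importlib

import numpy as np
import pytest

import enosecast as ec

fc = importlib.import_module("enosecast.forecast")
from enosecast.errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    ParameterError,
)
from enosecast.forecast import EPSILON0_COEFFS, GasModel
from enosecast.network import NetworkTopology, random_params, train_gd
from enosecast.types import GasSeries


def epsilon0_oracle(x):
    """Independent term-by-term summation of the gate polynomial."""
    degrees = range(8, -1, -1)
    return sum(c * x**d for c, d in zip(EPSILON0_COEFFS, degrees))


def small_run_config(seed=0, windows=(2,)):
    return ec.ForecastRunConfig(
        candidate_windows=windows, t0=len(windows), ssa_pop=10, ssa_iter=10, seed=seed
    )


@pytest.fixture(scope="module")
def quiet_series(quiet_config):
    return ec.simulate_storage_series(quiet_config, sample_seed=1)


class TestEpsilon0:
    def test_constant_term(self):
        assert ec.epsilon0(0) == pytest.approx(-0.2368, abs=0)

    def test_matches_summation_oracle(self):
        for x in range(13):
            assert ec.epsilon0(x) == pytest.approx(epsilon0_oracle(x), abs=1e-12)

    def test_known_values(self):
        assert ec.epsilon0(1) == pytest.approx(0.899373316, abs=1e-9)
        assert ec.epsilon0(4) == pytest.approx(0.916654336, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            ec.epsilon0(-1)


class TestRSquared:
    def test_hand_case(self):
        assert ec.r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_perfect_prediction(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert ec.r_squared(y, y) == 1.0

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert ec.r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_invariant_under_shared_affine_rescaling(self):
        rng = np.random.default_rng(0)
        y, f = rng.normal(size=25), rng.normal(size=25)
        base = ec.r_squared(y, f)
        for a, b in ((2.0, 1.0), (-0.5, 3.0), (10.0, -7.0)):
            assert ec.r_squared(a * y + b, a * f + b) == pytest.approx(base, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            ec.r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestBuildWindows:
    def test_forty_day_series_window_four_gives_36_pairs(self):
        win = ec.build_windows(np.arange(40.0), 4)
        assert win.n_pairs == 36

    def test_first_pair_targets_day_after_window(self):
        v = np.arange(10.0) * 2
        win = ec.build_windows(v, 3)
        np.testing.assert_array_equal(win.inputs[0], v[:3])
        assert win.targets[0] == v[3]

    def test_window_equal_to_length_rejected(self):
        with pytest.raises(InsufficientDataError):
            ec.build_windows(np.arange(5.0), 5)

    def test_normalization_bounds_applied(self):
        v = np.linspace(10, 20, 8)
        win = ec.build_windows(v, 2, bounds=(10, 20))
        assert win.inputs.min() == 0.0 and win.targets.max() == 1.0


class TestFitForecaster:
    def test_gate_contract_and_quality_on_quiet_series(self, quiet_series):
        model = ec.fit_forecaster(quiet_series, small_run_config(seed=1))
        if model.gate_status == "passed":
            assert model.eps > model.eps0
        assert model.eps > 0.95  # noise-free dynamics are learnable

    def test_deterministic_under_seed(self, quiet_series):
        a = ec.fit_forecaster(quiet_series, small_run_config(seed=3))
        b = ec.fit_forecaster(quiet_series, small_run_config(seed=3))
        assert a.eps == b.eps
        for g in a.models:
            np.testing.assert_array_equal(
                ec.params_to_vector(a.models[g].params),
                ec.params_to_vector(b.models[g].params),
            )

    def test_epsilon_computed_on_heldout_pairs_only(self, quiet_series, monkeypatch):
        """The reported R^2 must be scored on the chronological tail."""
        seen = []
        real = fc.r_squared

        def spy(y_true, y_pred):
            seen.append(np.asarray(y_true, dtype=float))
            return real(y_true, y_pred)

        monkeypatch.setattr(fc, "r_squared", spy)
        rc = small_run_config(seed=0)
        ec.fit_forecaster(quiet_series, rc)
        assert seen, "r_squared was never called"
        x = rc.candidate_windows[0]
        for g, y_seen in zip(quiet_series.values, seen):
            v = quiet_series.values[g]
            n_pairs = len(v) - x
            n_train = int(np.floor(rc.train_frac * n_pairs))
            span = v[: x + n_train]
            expected_tail = (v[x + n_train :] - span.min()) / (span.max() - span.min())
            np.testing.assert_allclose(y_seen, expected_tail, atol=1e-12)

    def test_too_short_series_rejected(self):
        short = GasSeries("s", np.arange(1, 4), {g: np.linspace(1, 2, 3) for g in ec.GASES})
        with pytest.raises(InsufficientDataError):
            ec.fit_forecaster(short, ec.ForecastRunConfig(candidate_windows=(5, 8)))


def constant_gas_model(c=50.0, x=2, lo=40.0, hi=60.0, gas="ethanol"):
    """A per-gas model trained to convergence on a constant (normalized 0.5)."""
    topo = NetworkTopology(x, 5, 1)
    xtr = np.full((20, x), 0.5)
    ytr = np.full((20, 1), 0.5)
    params, _ = train_gd(xtr, ytr, topology=topo, learning_rate=0.5, epochs=3000, seed=0)
    return GasModel(gas=gas, params=params, x=x, lo=lo, hi=hi, eps=1.0, train_mse=0.0, eval_mse=0.0)


class TestForecast:
    def make_model(self, gm):
        return ec.ForecastModel(models={gm.gas: gm}, x=gm.x, eps=1.0, eps0=0.9, gate_status="passed")

    def test_zero_horizon_empty(self):
        gm = constant_gas_model()
        series = GasSeries("s", np.arange(1, 6), {"ethanol": np.full(5, 50.0)})
        out = ec.forecast(self.make_model(gm), series, 0)
        assert out["ethanol"].size == 0

    def test_single_step_equals_one_forward_pass(self, quiet_series):
        model = ec.fit_forecaster(quiet_series, small_run_config(seed=2))
        out = ec.forecast(model, quiet_series, 1)
        for g, gm in model.models.items():
            window = ec.minmax_scale(quiet_series.values[g][-gm.x:], gm.lo, gm.hi)
            manual = float(ec.forward(gm.params, window)[0])
            expected = float(ec.minmax_unscale(manual, gm.lo, gm.hi))
            assert out[g][0] == pytest.approx(np.clip(expected, *ec.SENSOR_RANGES[g]))

    def test_constant_series_forecast_stays_constant(self):
        gm = constant_gas_model(c=50.0)
        series = GasSeries("s", np.arange(1, 8), {"ethanol": np.full(7, 50.0)})
        out = ec.forecast(self.make_model(gm), series, 5)
        assert np.all(np.abs(out["ethanol"] - 50.0) / 50.0 < 0.02)

    def test_monotone_series_direction_preserved(self, quiet_series):
        model = ec.fit_forecaster(quiet_series, small_run_config(seed=4))
        hist = GasSeries(
            "s",
            quiet_series.days[:20],
            {g: v[:20] for g, v in quiet_series.values.items()},
        )
        out = ec.forecast(model, hist, 3)
        for g in ("ethanol", "co2"):  # rising gases keep rising for >= 3 steps
            path = np.concatenate([[hist.values[g][-1]], out[g]])
            assert np.all(np.diff(path) > -1e-6)

    def test_negative_horizon_rejected(self):
        gm = constant_gas_model()
        series = GasSeries("s", np.arange(1, 6), {"ethanol": np.full(5, 50.0)})
        with pytest.raises(ParameterError):
            ec.forecast(self.make_model(gm), series, -1)


class TestCompareOptimized:
    def test_report_structure_and_reproducibility(self, quiet_series):
        rc = small_run_config(seed=5)
        rep = ec.compare_optimized(quiet_series, rc)
        assert [r["variant"] for r in rep.rows] == ["plain-bp", "tent-ssa-bp"]
        assert len(rep.as_table()) == 2
        rep2 = ec.compare_optimized(quiet_series, rc)
        for r, r2 in zip(rep.rows, rep2.rows):
            assert r["eps"] == r2["eps"] and r["eval_mse"] == r2["eval_mse"]
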