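"""Tent-SSA optimizer: tent map, carrier init, role updates, convergence."""
import numpy as np
import pytest

import enosecast as ec
from enosecast.errors import ConfigError, ObjectiveError, ParameterError
from enosecast.ssa import SSAState, tent_sequence


def sphere(x):
    return float(np.sum(x**2))


class TestTentSequence:
    def test_first_iterates(self):
        assert tent_sequence(0.3, 1)[0] == pytest.approx(0.6)
        assert tent_sequence(0.6, 1)[0] == pytest.approx(0.8)

    def test_range_preserved(self):
        for z0 in (0.123, 0.457, 0.911):
            z = tent_sequence(z0, 500, np.random.default_rng(0))
            assert np.all((z >= 0) & (z <= 1))

    def test_trap_values_are_nudged(self):
        # 0.125 -> 0.25 -> 0.5 -> 1 -> 0 would collapse without the nudge
        z = tent_sequence(0.125, 200, np.random.default_rng(0))
        assert np.std(z[5:]) > 0.1, "sequence must not collapse to a fixed point"

    @pytest.mark.parametrize("z0", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_seed_rejected(self, z0):
        with pytest.raises(ParameterError):
            tent_sequence(z0, 5)


class TestInitPopulation:
    def test_shape_and_bounds(self):
        cfg = ec.SSAConfig(dim=3, lb=[-1, 0, 5], ub=[1, 2, 9], n_pop=20, seed=1)
        pop = ec.init_population(cfg)
        assert pop.positions.shape == (20, 3)
        assert np.all(pop.positions >= cfg.lb) and np.all(pop.positions <= cfg.ub)

    def test_carrier_endpoints(self):
        # the carrier transform maps Z=0 -> lb and Z=1 -> ub
        lb, ub = np.array([-2.0]), np.array([6.0])
        assert lb + (ub - lb) * 0.0 == pytest.approx(lb)
        assert lb + (ub - lb) * 1.0 == pytest.approx(ub)

    def test_tent_init_spreads_more_than_degenerate_midpoint(self):
        cfg = ec.SSAConfig(dim=4, lb=-5, ub=5, n_pop=25, seed=2)
        pop = ec.init_population(cfg)
        d = np.linalg.norm(pop.positions[:, None] - pop.positions[None, :], axis=-1)
        assert d[np.triu_indices(25, 1)].mean() > 0.5  # midpoint init would give 0

    def test_config_invariants(self):
        with pytest.raises(ConfigError):
            ec.SSAConfig(dim=2, lb=1.0, ub=1.0)
        with pytest.raises(ConfigError):
            ec.SSAConfig(dim=2, n_pop=10, pnum=10)
        with pytest.raises(ConfigError):
            ec.SSAConfig(dim=2, st=0.4)


class TestGaussianMutate:
    def test_formula_cases(self):
        assert ec.gaussian_mutate(2.0, 0.5) == pytest.approx(3.0)
        assert ec.gaussian_mutate(5.0, 0.0) == pytest.approx(5.0)
        assert ec.gaussian_mutate(0.0, 1.7) == 0.0

    def test_clamped_to_bounds(self):
        assert ec.gaussian_mutate(2.0, 5.0, lb=-3, ub=3) == 3.0


class TestOptimize:
    def test_sphere_benchmark(self):
        hits = 0
        for seed in range(10):
            cfg = ec.SSAConfig(dim=2, lb=-5, ub=5, n_pop=30, max_iter=100, seed=seed)
            res = ec.optimize(sphere, cfg)
            hits += res.fg < 1e-3
            assert np.all(np.diff(res.history) <= 0)
            assert res.iterations <= cfg.max_iter
        assert hits >= 9

    def test_bit_identical_under_fixed_seed(self):
        cfg = ec.SSAConfig(dim=3, lb=-2, ub=2, n_pop=15, max_iter=30, seed=7)
        a, b = ec.optimize(sphere, cfg), ec.optimize(sphere, cfg)
        np.testing.assert_array_equal(a.xb, b.xb)
        assert a.fg == b.fg
        np.testing.assert_array_equal(a.history, b.history)

    def test_accuracy_stop(self):
        cfg = ec.SSAConfig(dim=2, lb=-5, ub=5, n_pop=30, max_iter=200, epsilon=1e-2, seed=3)
        res = ec.optimize(sphere, cfg)
        assert res.stop_reason == "accuracy"
        assert res.fg <= 1e-2
        assert res.iterations < 200

    def test_constant_objective_degenerate(self):
        cfg = ec.SSAConfig(dim=2, lb=-1, ub=1, n_pop=10, max_iter=5, seed=0)
        res = ec.optimize(lambda x: 1.0, cfg)
        assert res.fg == 1.0
        assert res.stop_reason == "max_iter"

    def test_history_non_increasing_across_objectives_and_seeds(self):
        objectives = [
            sphere,
            lambda x: float(np.sum(np.abs(x))),
            lambda x: float(10 * len(x) + np.sum(x**2 - 10 * np.cos(2 * np.pi * x))),
        ]
        for f in objectives:
            for seed in (0, 1, 2):
                cfg = ec.SSAConfig(dim=3, lb=-5.12, ub=5.12, n_pop=12, max_iter=25, seed=seed)
                res = ec.optimize(f, cfg)
                assert np.all(np.diff(res.history) <= 0)
                assert res.fg == res.history[-1]

    def test_non_finite_objective_raises(self):
        cfg = ec.SSAConfig(dim=2, lb=-1, ub=1, n_pop=8, max_iter=3, seed=0)
        with pytest.raises(ObjectiveError, match="individual"):
            ec.optimize(lambda x: float("nan"), cfg)

    def test_positions_stay_in_bounds_each_step(self):
        cfg = ec.SSAConfig(dim=2, lb=-1, ub=1, n_pop=12, max_iter=1, seed=4)
        rng = np.random.default_rng(cfg.seed)
        pop = ec.init_population(cfg, rng)
        pop.fitness = np.array([sphere(x) for x in pop.positions])
        ib, iw = int(np.argmin(pop.fitness)), int(np.argmax(pop.fitness))
        state = SSAState(
            xb=pop.positions[ib].copy(), fg=float(pop.fitness[ib]),
            xw=pop.positions[iw].copy(), fw=float(pop.fitness[iw]),
        )
        before = state.fg
        for it in range(1, 6):
            pop = ec.ssa_step(pop, sphere, it, cfg, rng, state)
            assert np.all(pop.positions >= cfg.lb) and np.all(pop.positions <= cfg.ub)
        assert state.fg <= before  # elitist best never worsens


class TestCanonicalToggle:
    def test_disabling_chaos_yields_canonical_ssa(self):
        base = dict(dim=2, lb=-5, ub=5, n_pop=20, max_iter=40, seed=5)
        cfg = ec.SSAConfig(**base, tent_init=False, chaotic_disturbance=False, gaussian_mutation=False)
        res = ec.optimize(sphere, cfg)
        # no chaotic phases fired, the run is deterministic and still sane
        assert res.stats["disturb_accepted"] == 0
        assert res.stats["mutate_accepted"] == 0
        res2 = ec.optimize(sphere, cfg)
        np.testing.assert_array_equal(res.history, res2.history)
        assert np.all(np.diff(res.history) <= 0)

    def test_chaotic_phases_fire_when_enabled(self):
        cfg = ec.SSAConfig(dim=2, lb=-5, ub=5, n_pop=20, max_iter=40, seed=5)
        res = ec.optimize(sphere, cfg)
        assert res.stats["disturb_accepted"] + res.stats["mutate_accepted"] > 0
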