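"""Synthetic-data generator: templates, sessions, dielectric labels, datasets."""
import dataclasses

import numpy as np
import pytest

import enosecast as ec
from enosecast.errors import BoundsError, ConfigError, ParameterError, RangeError
from enosecast.simulate import storage_template
from enosecast.types import GASES, SENSOR_RANGES, FreshnessLabel


class TestStorageSeries:
    def test_zero_noise_equals_template_and_is_seed_independent(self, quiet_config):
        a = ec.simulate_storage_series(quiet_config, sample_seed=1)
        b = ec.simulate_storage_series(quiet_config, sample_seed=2)
        for g in GASES:
            np.testing.assert_array_equal(a.values[g], storage_template(g, quiet_config))
            np.testing.assert_array_equal(a.values[g], b.values[g])

    def test_day_one_o2_template_is_start_level(self, default_config):
        assert storage_template("o2", default_config)[0] == pytest.approx(20.9, abs=0)

    def test_template_shapes(self, default_config):
        o2 = storage_template("o2", default_config)
        assert np.all(np.diff(o2) <= 0), "O2 is consumed: monotone non-increasing"
        for g in ("ethanol", "co2"):
            assert np.all(np.diff(storage_template(g, default_config)) >= 0)
        eth = storage_template("ethylene", default_config)
        peak_day = int(np.argmax(eth)) + 1
        assert peak_day == default_config.trajectories["ethylene"].mid_day
        assert np.all(np.diff(eth[: peak_day - 1]) > 0) and np.all(np.diff(eth[peak_day - 1 :]) < 0)

    def test_seeded_determinism(self, default_config):
        a = ec.simulate_storage_series(default_config, sample_seed=5)
        b = ec.simulate_storage_series(default_config, sample_seed=5)
        for g in GASES:
            np.testing.assert_array_equal(a.values[g], b.values[g])

    def test_noise_clipped_to_sensor_range(self, default_config):
        noisy = dataclasses.replace(default_config).with_noise(daily_frac=0.5)
        s = ec.simulate_storage_series(noisy, sample_seed=3)
        for g in GASES:
            lo, hi = SENSOR_RANGES[g]
            assert np.all((s.values[g] >= lo) & (s.values[g] <= hi))

    def test_invalid_shape_rejected(self):
        with pytest.raises(ConfigError, match="shape"):
            ec.GasTrajectory(start=30, end=300, shape="spline")


class TestSession:
    def test_default_session_has_900_samples(self, quiet_config):
        plateau = {"ethanol": 200.0, "co2": 2000.0, "o2": 18.0, "ethylene": 30.0}
        sess = ec.simulate_session(plateau, quiet_config, seed=0)
        assert sess.n_samples == 900
        assert all(len(v) == 900 for v in sess.channels.values())

    def test_first_order_response_at_three_tau(self, quiet_config):
        plateau = {"ethanol": 300.0, "co2": 2000.0, "o2": 18.0, "ethylene": 30.0}
        sess = ec.simulate_session(plateau, quiet_config, seed=0)
        i = int(3 * quiet_config.tau * quiet_config.sampling_rate)  # t = 3 tau
        expected = (1.0 - np.exp(-3.0)) * 300.0
        assert sess.channels["ethanol"][i] == pytest.approx(expected, rel=1e-12)

    def test_final_samples_approach_plateau(self, quiet_config):
        plateau = {"ethanol": 300.0, "co2": 2000.0, "o2": 18.0, "ethylene": 30.0}
        sess = ec.simulate_session(plateau, quiet_config, seed=0)
        for g, p in plateau.items():
            assert sess.channels[g][-1] == pytest.approx(p, rel=1e-4)

    def test_plateau_outside_range_rejected(self, default_config):
        bad = {"ethanol": 600.0, "co2": 2000.0, "o2": 18.0, "ethylene": 30.0}
        with pytest.raises(RangeError, match="ethanol"):
            ec.simulate_session(bad, default_config)


class TestDielectric:
    def test_day_one_lies_in_fresh_row(self, default_config):
        m = ec.simulate_dielectric(1, default_config)
        assert 2.0 <= m.cs <= 2.5
        assert 6.1 <= m.d <= 6.8
        assert 5.0 <= m.er <= 5.5

    def test_final_day_labels_decay(self, default_config):
        assert ec.label_of_day(default_config.n_days, default_config) is FreshnessLabel.DECAY

    def test_capacitance_non_increasing_in_day(self, default_config):
        cs = [ec.simulate_dielectric(d, default_config).cs for d in range(1, 41)]
        assert np.all(np.diff(cs) <= 0)

    def test_label_weakly_monotone_in_day(self, default_config):
        labels = [int(ec.label_of_day(d, default_config)) for d in range(1, 41)]
        assert np.all(np.diff(labels) >= 0)
        assert set(labels) == {0, 1, 2}

    @pytest.mark.parametrize("day", [0, 41, -3])
    def test_day_out_of_span_rejected(self, default_config, day):
        with pytest.raises(BoundsError):
            ec.simulate_dielectric(day, default_config)


class TestDataset:
    def test_standard_design_180_samples(self, default_config):
        ds = ec.generate_dataset(default_config, n_samples=180, seed=7, keep_series=False)
        assert ds.features.shape == (180, 4)
        assert len(ds.labels) == 180
        train, test = ec.split_dataset(ds, train_frac=0.8, seed=7)
        assert (len(train), len(test)) == (144, 36)

    def test_all_three_labels_present(self, small_dataset):
        assert {int(l) for l in small_dataset.labels} == {0, 1, 2}

    def test_deterministic_under_seed(self, default_config):
        a = ec.generate_dataset(default_config, n_samples=8, seed=4, keep_series=False)
        b = ec.generate_dataset(default_config, n_samples=8, seed=4, keep_series=False)
        np.testing.assert_array_equal(a.features, b.features)
        assert a.labels == b.labels
        np.testing.assert_array_equal(a.days, b.days)

    def test_features_within_sensor_ranges(self, small_dataset):
        for j, g in enumerate(GASES):
            lo, hi = SENSOR_RANGES[g]
            col = small_dataset.features[:, j]
            assert np.all((col >= lo) & (col <= hi))

    def test_features_track_series_day_value(self, quiet_config):
        # noise-free: the extracted stable feature matches the day's series value
        ds = ec.generate_dataset(quiet_config, n_samples=4, seed=1)
        for i in range(4):
            day = ds.days[i]
            for j, g in enumerate(GASES):
                assert ds.features[i, j] == pytest.approx(
                    ds.series[i].values[g][day - 1], rel=0.01
                )

    def test_rejects_empty_request(self, default_config):
        with pytest.raises(ParameterError):
            ec.generate_dataset(default_config, n_samples=0)
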