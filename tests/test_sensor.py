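"""Windowing, scaling, loss, architecture and training behavior."""

import numpy as np
import pytest

from fermsense.errors import (ContractError, InvalidInputError,
                              TrainingDivergedError)
from fermsense.nn import LSTMNet
from fermsense.sensor import (MinMaxScaler, SensorConfig, apply_scaler,
                              build_sensor, concat_windows, fit_scaler,
                              invert_scaler, load_sensor, make_windows,
                              mmse_loss, predict, save_sensor, train_sensor,
                              train_sensors, TrainedSensor)


def toy_dataset(n_exp=5, n=40, seed=0, target_fn=None, window=23):
    """Experiments with random-phase sinusoidal excitation of one feature."""
    rng = np.random.default_rng(seed)
    parts = []
    for e in range(n_exp):
        t = np.linspace(0, 10, n)
        f = np.sin(0.5 * t + rng.uniform(0, 2 * np.pi)) + 1.5
        y = target_fn(f) if target_fn else 2.0 * f
        parts.append(make_windows(f, y, window, experiment_id=f"e{e}",
                                  times=t, feature_names=["f"]))
    return concat_windows(parts)


class TestWindows:
    def test_edge_padding_yields_one_window_per_instant(self):
        ds = make_windows(np.arange(23.0), np.arange(23.0), 23)
        assert len(ds) == 23
        assert ds.X.shape == (23, 23, 1)

    def test_strict_mode_drops_leading_instants(self):
        ds = make_windows(np.arange(23.0), np.arange(23.0), 23, padding="strict")
        assert len(ds) == 1
        np.testing.assert_array_equal(ds.X[0, :, 0], np.arange(23.0))

    def test_constant_series_gives_identical_windows(self):
        ds = make_windows(np.full(30, 3.3), np.zeros(30), 10)
        assert np.ptp(ds.X) == 0

    def test_windows_never_span_experiments(self):
        a = make_windows(np.arange(30.0), np.zeros(30), 5, experiment_id="a")
        b = make_windows(np.arange(30.0) + 100, np.zeros(30), 5, experiment_id="b")
        ds = concat_windows([a, b])
        for w, eid in zip(ds.X, ds.exp_ids):
            assert np.all(w >= 100) if eid == "b" else np.all(w < 100)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            make_windows(np.zeros((10, 2)), np.zeros(9), 5)

    def test_at_indices_restricts_to_assayed_instants(self):
        ds = make_windows(np.arange(50.0), np.arange(50.0), 8,
                          at_indices=[5, 20, 45])
        assert len(ds) == 3
        np.testing.assert_array_equal(ds.y, [5, 20, 45])


class TestScaler:
    def test_maps_to_unit_interval(self):
        sc = fit_scaler(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(apply_scaler(sc, np.array([[2.], [4.], [6.]])),
                                   [[0.0], [0.5], [1.0]])

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(50, 4)) * 10
        sc = fit_scaler(m)
        np.testing.assert_allclose(invert_scaler(sc, apply_scaler(sc, m)), m,
                                   atol=1e-12)

    def test_out_of_range_values_exceed_unit_interval(self):
        sc = fit_scaler(np.array([[0.0], [1.0]]))
        assert apply_scaler(sc, np.array([[2.0]]))[0, 0] == 2.0  # no clipping

    def test_constant_feature_convention(self):
        sc = fit_scaler(np.array([[5.0], [5.0]]))
        assert sc.scale[0] == 1.0
        assert apply_scaler(sc, np.array([[5.0]]))[0, 0] == 0.0


class TestLoss:
    def test_perfect_prediction_gives_one(self):
        assert mmse_loss([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_unit_error_gives_four(self):
        assert mmse_loss([2.0], [1.0]) == pytest.approx(4.0)

    def test_linear_variant(self):
        assert mmse_loss([2.0], [1.0], variant="mmse_linear") == pytest.approx(1.0)
        assert mmse_loss([1.0], [1.0], variant="mmse_linear") == pytest.approx(0.5)

    def test_strictly_increasing_in_error(self):
        errors = np.linspace(0, 3, 13)
        losses = [mmse_loss([1.0 + e], [1.0]) for e in errors]
        assert np.all(np.diff(losses) > 0)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            mmse_loss([], [])


class TestArchitecture:
    def test_parameter_counts(self):
        for F in (3, 8):
            net = build_sensor(SensorConfig(), n_features=F)
            lstm = 4 * 23 * (F + 23 + 1)
            dense = (23 * 10 + 10) + (10 * 1 + 1)
            assert net.count_params() == lstm + dense

    def test_output_nonnegative_for_arbitrary_inputs(self):
        rng = np.random.default_rng(2)
        net = build_sensor(SensorConfig(seed=3), n_features=4)
        X = rng.normal(scale=5.0, size=(17, 23, 4))
        assert np.all(net.forward(X) >= 0)

    def test_same_seed_same_initial_weights(self):
        a = build_sensor(SensorConfig(seed=9), n_features=5)
        b = build_sensor(SensorConfig(seed=9), n_features=5)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_zero_weights_give_constant_nonnegative_output(self):
        net = build_sensor(SensorConfig(), n_features=2)
        for k in net.params:
            net.params[k][...] = 0.0
        out = net.forward(np.random.default_rng(0).normal(size=(6, 23, 2)))
        assert np.ptp(out) == 0 and np.all(out >= 0)


class TestTraining:
    def test_learns_noiseless_linear_target(self):
        """A linear map of one feature is fitted to < 0.05 g/L MAE.

        Dropout is disabled here: the check isolates the trainer's learning
        signal from regularization noise on a separable problem.
        """
        ds = toy_dataset(n_exp=5, n=40)   # 200 points
        cfg = SensorConfig(max_epochs=1000, patience=100, seed=1,
                           dropout_rate=0.0, learning_rate=3e-3)
        trained = train_sensor(ds, cfg)
        val_mask = ~np.isin(ds.exp_ids, list(trained.split["train"]))
        est = predict(trained, ds)
        assert np.mean(np.abs(est[val_mask] - ds.y[val_mask])) < 0.05

    def test_early_stopping_triggers(self):
        ds = toy_dataset(n_exp=4, n=30)
        trained = train_sensor(ds, SensorConfig(max_epochs=1000, patience=20, seed=2))
        assert len(trained.history) < 1000

    def test_split_is_by_experiment(self):
        ds = toy_dataset(n_exp=5, n=30)
        trained = train_sensor(ds, SensorConfig(max_epochs=2, seed=0))
        assert trained.split["train"] & trained.split["val"] == set()
        assert trained.split["train"] | trained.split["val"] == set(ds.exp_ids)

    def test_shuffled_target_control_cannot_beat_mean(self):
        """With permuted targets, sensors do no better than the train mean."""
        ds = toy_dataset(n_exp=5, n=30, seed=3)
        rng = np.random.default_rng(7)
        ds.y = rng.permutation(ds.y)
        ratios = []
        for seed in range(5):
            cfg = SensorConfig(max_epochs=40, patience=40, seed=seed)
            trained = train_sensor(ds, cfg)
            val_mask = ~np.isin(ds.exp_ids, list(trained.split["train"]))
            est = predict(trained, ds)[val_mask]
            obs = ds.y[val_mask]
            model_mae = np.mean(np.abs(est - obs))
            mean_mae = np.mean(np.abs(ds.y[~val_mask].mean() - obs))
            ratios.append(model_mae / mean_mae)
        assert np.median(ratios) > 0.9

    def test_divergence_raises_with_epoch(self):
        ds = toy_dataset(n_exp=3, n=20)
        cfg = SensorConfig(max_epochs=5, learning_rate=1e12, seed=0)
        with pytest.raises(TrainingDivergedError):
            train_sensor(ds, cfg)


class TestStackedTrials:
    def test_stacked_matches_architecture_and_count(self):
        ds = toy_dataset(n_exp=4, n=30)
        cfgs = [SensorConfig(max_epochs=3, seed=s) for s in (1, 2)]
        out = train_sensors(ds, cfgs)
        assert len(out) == 2
        assert out[0].net.count_params() == out[1].net.count_params()

    def test_column_slicing_trains_on_named_subsets(self):
        rng = np.random.default_rng(0)
        parts = []
        for e in range(4):
            t = np.linspace(0, 10, 30)
            f = np.column_stack([np.sin(t + e), np.cos(t), t])
            parts.append(make_windows(f, f[:, 0] + 2, 8, experiment_id=f"e{e}",
                                      times=t, feature_names=["a", "b", "c"]))
        ds = concat_windows(parts)
        cfgs = [SensorConfig(max_epochs=2, window_steps=8, seed=s) for s in (1, 2)]
        out = train_sensors(ds, cfgs, columns=[[0, 1], [1, 2]])
        assert out[0].feature_names == ["a", "b"]
        assert out[1].feature_names == ["b", "c"]


class TestPredictAndPersist:
    def test_prediction_length_and_nonnegativity(self):
        ds = toy_dataset(n_exp=3, n=25)
        trained = train_sensor(ds, SensorConfig(max_epochs=3, seed=1))
        est = predict(trained, ds)
        assert est.shape == (len(ds),)
        assert np.all(est >= 0)

    def test_feature_mismatch_rejected(self):
        ds = toy_dataset(n_exp=3, n=25)
        trained = train_sensor(ds, SensorConfig(max_epochs=2, seed=1))
        bad = make_windows(np.zeros((10, 1)), np.zeros(10), 23,
                           feature_names=["other"])
        with pytest.raises(ContractError):
            predict(trained, bad)

    def test_save_load_round_trip(self, tmp_path):
        ds = toy_dataset(n_exp=3, n=25)
        trained = train_sensor(ds, SensorConfig(max_epochs=3, seed=4))
        save_sensor(trained, tmp_path / "sensor")
        loaded = load_sensor(tmp_path / "sensor")
        np.testing.assert_allclose(predict(loaded, ds), predict(trained, ds),
                                   atol=1e-12)
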