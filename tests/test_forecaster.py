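"""Windowing, normalization, architecture and training mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermentforge import forecaster as fc
from fermentforge._lstm import VLSTM, lstm_param_count


class TestMinMax:
    def test_basic_map(self):
        bounds = np.array([[0.0, 10.0]])
        vals = np.array([[0.0], [5.0], [10.0]])
        assert np.allclose(fc.minmax_apply(vals, bounds).ravel(), [0, 0.5, 1])

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(scale=40, size=(100, 4))
        bounds = np.stack([vals.min(0), vals.max(0)], axis=1)
        back = fc.minmax_invert(fc.minmax_apply(vals, bounds), bounds)
        assert np.allclose(back, vals, atol=1e-9)

    def test_out_of_range_extrapolates_without_clipping(self):
        bounds = np.array([[0.0, 10.0]])
        assert fc.minmax_apply(np.array([12.0]), bounds)[0] == pytest.approx(1.2)

    def test_constant_attribute_widened(self):
        with pytest.warns(UserWarning):
            bounds = fc.minmax_fit([np.full((10, 2), 3.0)])
        assert np.all(bounds[:, 1] > bounds[:, 0])

    def test_attribute_count_mismatch(self):
        with pytest.raises(ValueError):
            fc.minmax_apply(np.zeros((3, 2)), np.zeros((4, 2)))


class TestWindowing:
    @pytest.mark.parametrize(
        "T, stride, expected",
        [(600, 12, 3), (576, 1, 1), (575, 1, 0)],
    )
    def test_reference_counts(self, T, stride, expected):
        assert fc.window_count(T, 288, 288, stride) == expected

    def test_short_curve_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning):
            ds = fc.make_windows([rng.random((100, 3))], nt=288, pl=288)
        assert len(ds) == 0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        T=st.integers(5, 300),
        nt=st.integers(1, 40),
        pl=st.integers(1, 40),
        stride=st.integers(1, 30),
    )
    def test_count_formula_matches_enumeration(self, T, nt, pl, stride):
        starts = [s for s in range(0, T, stride) if s + nt + pl <= T]
        # brute force: every stride offset whose window fits
        brute = sum(1 for s in range(0, T - nt - pl + 1) if s % stride == 0)
        assert len(starts) == brute == fc.window_count(T, nt, pl, stride)

    def test_window_contents_and_provenance(self):
        mat = np.arange(40, dtype=float).reshape(20, 2)
        ds = fc.make_windows([mat, mat + 100], nt=4, pl=2, stride=3)
        raw = fc.minmax_invert(ds.inputs[0], ds.norm_bounds)
        assert np.allclose(raw, mat[:4])
        assert set(ds.source_curve_ids) == {0, 1}

    def test_split_is_disjoint_and_seeded(self):
        mat = np.random.default_rng(1).random((60, 2))
        ds = fc.make_windows([mat], nt=5, pl=3, stride=1)
        rest, held = ds.split(0.2, seed=4)
        assert len(rest) + len(held) == len(ds)
        again_rest, again_held = ds.split(0.2, seed=4)
        assert np.array_equal(held.inputs, again_held.inputs)


class TestArchitecture:
    def test_output_shape_under_reference_config(self):
        model = fc.build_model(8, 1, 288, 288, 6, seed=0)
        out = model.forward(np.zeros((2, 288, 6)), training=False)
        assert out.shape == (2, 288, 6)

    def test_minimal_model_trains_one_step(self):
        model = fc.build_model(1, 1, 4, 2, 1, seed=0)
        x = np.random.default_rng(0).random((8, 4, 1))
        y = np.random.default_rng(1).random((8, 2, 1))
        hist = model.fit(x, y, epochs=1, batch_size=4, seed=0)
        assert hist["epochs_ran"] == 1

    def test_recurrent_parameter_count_oracle(self):
        # standard LSTM formula 4·((D+H)·H + H)
        assert lstm_param_count(6, 64) == 4 * ((6 + 64) * 64 + 64) == 18176
        model = fc.build_model(64, 1, 10, 5, 6, seed=0, batch_norm=False)
        lstm_params = sum(p.size for layer in model.lstm_layers for p in layer.params())
        assert lstm_params == 18176

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            fc.build_model(0, 1, 4, 2, 1)

    def test_gradients_match_numerical_differentiation(self):
        model = VLSTM(cells=4, layers=2, nt=6, pl=3, k=2, seed=1, batch_norm=True)
        rng = np.random.default_rng(2)
        x = rng.random((5, 6, 2)).astype(np.float32)
        y = rng.random((5, 3, 2)).astype(np.float32)
        _, grads = model.loss_and_grads(x, y)
        params = model.parameters()
        checked = 0
        for pi in range(len(params)):
            p = params[pi]
            for fi in {0, p.size // 2, p.size - 1}:
                orig = p.flat[fi]
                eps = 1e-3
                p.flat[fi] = orig + eps
                up, _ = model.loss_and_grads(x, y)
                p.flat[fi] = orig - eps
                down, _ = model.loss_and_grads(x, y)
                p.flat[fi] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[pi].flat[fi]
                if abs(numeric) > 1e-4:
                    assert analytic == pytest.approx(numeric, rel=0.08, abs=1e-4)
                    checked += 1
        assert checked > 10

    def test_deterministic_inference_and_seeded_init(self):
        a = fc.build_model(4, 1, 6, 3, 2, seed=7)
        b = fc.build_model(4, 1, 6, 3, 2, seed=7)
        x = np.random.default_rng(0).random((3, 6, 2))
        assert np.array_equal(a.forward(x), b.forward(x))
        assert np.array_equal(a.forward(x), a.forward(x))

    def test_checkpoint_round_trip(self, tmp_path):
        model = fc.build_model(4, 2, 6, 3, 2, seed=0)
        x = np.random.default_rng(0).random((4, 6, 2))
        model.fit(x[:, :, :], np.random.default_rng(1).random((4, 3, 2)), epochs=2, seed=0)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = VLSTM.load(path)
        assert np.allclose(model.forward(x), loaded.forward(x), atol=1e-7)


class TestLayerPenalty:
    def test_two_candidate_hand_computation(self):
        penalties = fc.weighted_layer_loss([10.0, 20.0], [1, 10])
        assert np.allclose(penalties, [0.0, 1.0])

    def test_zero_at_min_rmse_and_min_layers(self):
        rmse = [5.0, 3.0, 4.0]
        layers = [1, 5, 10]
        p = fc.weighted_layer_loss(rmse, layers)
        assert p[0] == 0.0  # min layer count
        assert p[1] == 0.0  # min RMSE
        assert np.all((p >= 0) & (p <= 1))

    def test_constant_rmse_degenerates_to_zeros(self):
        with pytest.warns(UserWarning):
            p = fc.weighted_layer_loss([2.0, 2.0], [1, 2])
        assert np.all(p == 0)

    def test_bad_lengths(self):
        with pytest.raises(ValueError):
            fc.weighted_layer_loss([1.0], [1])


def tiny_dataset(seed=0, n_curves=3, T=60, k=2, nt=8, pl=4, stride=2):
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_curves):
        t = np.arange(T) / 7.0 + rng.uniform(0, 3)
        curves.append(np.stack([np.sin(t), np.cos(t)], axis=1)[:, :k] * 0.4 + 0.5)
    return fc.make_windows(curves, nt=nt, pl=pl, stride=stride)


class TestTuning:
    def test_cell_candidates_respect_range_and_spacing(self):
        rng = np.random.default_rng(3)
        cands = fc._sample_cell_candidates(rng, 32, 512, 10, 32)
        assert len(set(cands)) == 10
        assert cands.min() >= 32 and cands.max() <= 512
        assert np.all(np.diff(np.sort(cands)) >= 32)

    def test_infeasible_spacing_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            fc._sample_cell_candidates(rng, 32, 64, 10, 32)

    def test_cell_search_reproducible(self):
        ds = tiny_dataset()
        a = fc.tune_cells(ds, seed=5, cell_range=(4, 40), trials=3, min_spacing=4, epochs=1)
        b = fc.tune_cells(ds, seed=5, cell_range=(4, 40), trials=3, min_spacing=4, epochs=1)
        assert a.cell_trace == b.cell_trace
        assert a.best_cells == b.best_cells
        assert any(c == a.best_cells for c, _ in a.cell_trace)

    def test_layer_search_reports_penalties(self):
        ds = tiny_dataset()
        tuned = fc.tune_layers(ds, best_cells=4, seed=5, layer_range=(1, 3), epochs=1)
        assert 1 <= tuned.best_layers <= 3
        assert len(tuned.layer_trace) == 3
        for layer, rmse, penalty in tuned.layer_trace:
            assert 0.0 <= penalty <= 1.0


class TestTrainingMechanics:
    def test_learning_rate_reduces_by_quarter_on_plateau(self):
        """With an impossible improvement threshold every epoch is a
        plateau: the schedule must walk 1e-4, 2.5e-5, 6.25e-6, ..."""
        ds = tiny_dataset()
        model = fc.build_model(3, 1, 8, 4, 2, seed=0, batch_norm=False)
        hist = model.fit(
            ds.inputs,
            ds.labels,
            epochs=5,
            lr=1e-4,
            early_stop_patience=10,
            early_stop_min_delta=1e9,
            seed=0,
        )
        # the first epoch sets the incumbent; every later epoch plateaus
        assert hist["lr"] == pytest.approx([1e-4, 1e-4, 2.5e-5, 6.25e-6, 1.5625e-6])

    def test_early_stopping_triggers_on_plateau(self):
        ds = tiny_dataset()
        model = fc.build_model(3, 1, 8, 4, 2, seed=0, batch_norm=False)
        hist = model.fit(
            ds.inputs,
            ds.labels,
            epochs=100,
            early_stop_patience=5,
            early_stop_min_delta=1e9,
            seed=0,
        )
        assert hist["epochs_ran"] <= 6

    def test_chunked_training_carries_weights_and_skips_empty(self):
        ds = tiny_dataset(n_curves=6)
        idx = np.array_split(np.arange(len(ds)), 2)
        chunks = [ds.subset(idx[0]), ds.subset(np.array([], dtype=int)), ds.subset(idx[1])]
        model = fc.build_model(3, 1, 8, 4, 2, seed=0, batch_norm=False)
        w0 = [p.copy() for p in model.parameters()]
        cfg = fc.TrainingConfig(nt=8, pl=4, lr_initial=1e-2)
        with pytest.warns(UserWarning):
            hist = fc.train_chunked(model, chunks, config=cfg, seed=0, epochs=3)
        assert len(hist) == 2  # empty chunk skipped
        assert any(
            not np.array_equal(a, b) for a, b in zip(w0, model.parameters())
        )

    def test_forecast_shapes_and_normalization_round_trip(self):
        ds = tiny_dataset()
        model = fc.build_model(3, 1, 8, 4, 2, seed=0)
        window = fc.minmax_invert(ds.inputs[0], ds.norm_bounds)
        pred = fc.forecast(model, window, ds.norm_bounds)
        assert pred.shape == (4, 2)
        with pytest.raises(ValueError):
            fc.forecast(model, window[:3], ds.norm_bounds)

    def test_evaluate_perfect_oracle_is_zero(self):
        ds = tiny_dataset()

        class Oracle:
            def forward(self, x, training=False):
                return labels_lookup[: len(x)]

        # emulate perfection by evaluating the model's own labels
        labels_lookup = ds.labels
        model = Oracle()
        assert fc.evaluate(model, ds, batch_size=len(ds)) == pytest.approx(0.0, abs=1e-12)

    def test_evaluate_empty_rejected(self):
        ds = tiny_dataset().subset(np.array([], dtype=int))
        model = fc.build_model(3, 1, 8, 4, 2, seed=0)
        with pytest.raises(ValueError):
            fc.evaluate(model, ds)

    def test_learning_beats_mean_predictor_and_shuffled_labels(self):
        """A small model on smooth noise-free dynamics must beat the mean
        predictor, and shuffling the labels must destroy that skill."""
        ds = tiny_dataset(n_curves=6, T=120)
        rest, test = ds.split(0.25, seed=0)
        model = fc.build_model(12, 2, 8, 4, 2, seed=0, batch_norm=False)
        model.fit(rest.inputs, rest.labels, epochs=60, lr=5e-3, seed=0,
                  early_stop_patience=60)
        trained = fc.evaluate(model, test)
        mean_rmse = float(np.sqrt(np.mean((test.labels - rest.labels.mean((0, 1))) ** 2)))
        assert trained < 0.6 * mean_rmse

        rng = np.random.default_rng(0)
        shuffled = rest.labels[rng.permutation(len(rest))]
        noisy_model = fc.build_model(12, 2, 8, 4, 2, seed=0, batch_norm=False)
        noisy_model.fit(rest.inputs, shuffled, epochs=60, lr=5e-3, seed=0,
                        early_stop_patience=60)
        assert fc.evaluate(noisy_model, test) > trained
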