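import numpy as np
import pytest

from bruiseage.models import (
    CnnConfig,
    CnnSpec,
    LassoBaseline,
    TrainConfig,
    build_cnn,
    cnn_shape_trace,
    fit_lasso,
    load_checkpoint,
    save_checkpoint,
    spatial_average,
    train_model,
)
from conftest import make_patch_cohort

TOY_CONFIG = CnnConfig(
    n_bands=8, spectral_channels=(4, 4, 4), spatial_channels=(4, 8), head_hidden=16
)


class TestSpatialAverage:
    def test_constant_band(self):
        patch = np.zeros((2, 4, 4), dtype=np.float32)
        patch[0] = 0.3
        np.testing.assert_allclose(spatial_average(patch), [0.3, 0.0], atol=1e-7)

    def test_two_pixel_mean(self):
        patch = np.array([[[0.2, 0.4]]])
        assert spatial_average(patch)[0] == pytest.approx(0.3)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(3)
        patch = rng.random((5, 6, 7))
        oracle = np.zeros(5)
        for b in range(5):
            total = 0.0
            for i in range(6):
                for j in range(7):
                    total += patch[b, i, j]
            oracle[b] = total / 42
        np.testing.assert_allclose(spatial_average(patch), oracle, atol=1e-9)


class TestLassoBaseline:
    def test_constant_targets_predict_the_constant(self):
        rng = np.random.default_rng(0)
        X = rng.random((12, 6))
        model = fit_lasso(X, np.full(12, 7.0))
        np.testing.assert_allclose(model.predict(X), 7.0, atol=1e-8)

    def test_informative_band_selected_noise_bands_dropped(self):
        rng = np.random.default_rng(1)
        ages = np.tile(np.arange(8.0), 4)
        X = rng.normal(0, 0.05, size=(32, 10))
        X[:, 3] += ages * 0.1
        model = fit_lasso(X, ages, groups=np.repeat(np.arange(4), 8))
        assert 3 in model.nonzero_bands_
        other = [b for b in model.nonzero_bands_ if b != 3]
        assert np.all(np.abs(model.coef_[other]) < np.abs(model.coef_[3]) / 5)

    def test_infinite_penalty_limit_gives_intercept_only_model(self):
        rng = np.random.default_rng(2)
        X = rng.random((20, 5))
        y = rng.uniform(0, 20, 20)
        # alpha_min_ratio=1 collapses the grid onto alpha_max, where every
        # coefficient is zero by construction
        model = LassoBaseline(alpha_min_ratio=1.0, n_alphas=1).fit(X, y)
        assert model.nonzero_bands_.size == 0
        assert model.intercept_ == pytest.approx(y.mean())

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_lasso(np.zeros((1, 3)), np.zeros(1))


class TestCnnForward:
    def test_scalar_output_per_sample(self):
        model = build_cnn(TOY_CONFIG, seed=0)
        out = model.forward(np.random.default_rng(0).random((3, 8, 16, 16)))
        assert out.shape == (3,)
        assert np.all(np.isfinite(out))

    def test_band_mismatch_raises(self):
        model = build_cnn(TOY_CONFIG, seed=0)
        with pytest.raises(ValueError, match="expected"):
            model.forward(np.zeros((1, 9, 16, 16)))

    def test_flatten_width_is_band_count_independent(self):
        for bands in (8, 20, 60):
            cfg = CnnConfig(
                n_bands=bands, spectral_channels=(4, 4, 4), spatial_channels=(4, 8), head_hidden=16
            )
            assert cfg.flatten_width == 8 * 16
            out = build_cnn(cfg, seed=0).forward(np.zeros((1, bands, 16, 16), dtype=np.float32))
            assert out.shape == (1,)

    def test_duplicate_samples_get_identical_predictions(self):
        model = build_cnn(TOY_CONFIG, seed=0)
        x = np.random.default_rng(1).random((1, 8, 16, 16)).astype(np.float32)
        batch = np.concatenate([x, x])
        preds = model.predict(batch)
        assert preds[0] == preds[1]

    def test_prediction_order_preserved(self):
        model = build_cnn(TOY_CONFIG, seed=0)
        x = np.random.default_rng(2).random((5, 8, 16, 16)).astype(np.float32)
        full = model.predict(x, batch_size=2)
        singles = np.array([model.predict(x[i : i + 1])[0] for i in range(5)])
        np.testing.assert_allclose(full, singles, rtol=1e-4, atol=1e-5)

    def test_spectral_average_modes_agree_when_bands_divide_pool(self):
        rng = np.random.default_rng(3)
        x = rng.random((2, 16, 8, 8)).astype(np.float32)
        outs = []
        for mode in ("pool-then-mean", "direct"):
            cfg = CnnConfig(
                n_bands=16,
                spectral_channels=(3, 3, 3),
                spatial_channels=(4, 4),
                head_hidden=8,
                spectral_average=mode,
            )
            outs.append(build_cnn(cfg, seed=5).forward(x))
        # 16 bands split evenly into 16 pool bins, so pooling then averaging
        # equals averaging directly
        np.testing.assert_allclose(outs[0], outs[1], rtol=1e-5, atol=1e-5)


class TestShapeTrace:
    def test_phantom_preset_trace_is_consistent(self):
        trace = cnn_shape_trace(CnnConfig.phantom_preset(60), image_size=32)
        names = [t[0] for t in trace]
        assert names[0] == "input"
        assert names.count("conv1d") == 3
        assert trace[-1] == ("linear", (1,))


class TestTraining:
    def _toy_data(self, n=12, bands=8, p=8, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=(n, bands, p, p)).astype(np.float32)
        y = x[:, 0].mean(axis=(1, 2)) * 4.0 + 5.0
        return x, y.astype(np.float64)

    def _toy_cfg(self, p=8):
        return CnnConfig(
            n_bands=8, spectral_channels=(3, 3, 3), spatial_channels=(4, 4), head_hidden=8
        )

    def test_training_reduces_validation_mae(self):
        x, y = self._toy_data(16)
        model = build_cnn(self._toy_cfg(), seed=0)
        cfg = TrainConfig(learning_rate=3e-3, batch_size=4, max_epochs=12, patience=6, seed=0)
        history = train_model(model, x[:12], y[:12], x[12:], y[12:], cfg)
        assert min(history["val_mae"]) < history["val_mae"][0]

    def test_same_seed_reproduces_history_exactly(self):
        x, y = self._toy_data(10)
        cfg = TrainConfig(learning_rate=3e-3, batch_size=4, max_epochs=4, patience=2, seed=3)
        h1 = train_model(build_cnn(self._toy_cfg(), seed=1), x[:8], y[:8], x[8:], y[8:], cfg)
        h2 = train_model(build_cnn(self._toy_cfg(), seed=1), x[:8], y[:8], x[8:], y[8:], cfg)
        assert h1 == h2

    def test_empty_validation_set_rejected(self):
        x, y = self._toy_data(8)
        with pytest.raises(ValueError):
            train_model(
                build_cnn(self._toy_cfg(), seed=0),
                x,
                y,
                x[:0],
                y[:0],
                TrainConfig(max_epochs=2, patience=1),
            )

    def test_overfit_small_batch_sanity(self):
        """A standard overfit-one-batch check on 8 phantom-like samples
        (regularization off, so the network can memorize the batch)."""
        ds = make_patch_cohort(n_subjects=2, ages=(0, 4, 9, 16), n_bands=8, patch=8, seed=1)
        cfg = CnnConfig(
            n_bands=8,
            spectral_channels=(3, 3, 3),
            spatial_channels=(4, 4),
            head_hidden=8,
            dropout=0.0,
        )
        spec = CnnSpec(
            cnn_config=cfg,
            train_config=TrainConfig(
                learning_rate=1e-2,
                batch_size=8,
                max_epochs=200,
                patience=199,
                min_delta=0.0,
                augment_flips=False,
                weight_decay=0.0,
            ),
        )
        fitted = spec.fit(ds, ds, seed=0)  # validate on the training batch itself
        preds = fitted.predict(ds)
        assert np.mean(np.abs(preds - ds.ages())) < 0.5

    def test_flip_augmentation_neutral_on_symmetric_statistics(self):
        """On phantoms whose spatial statistics are flip-invariant, enabling
        flips must not shift validation MAE beyond seed noise (overlapping
        bootstrap intervals over 5 seeds)."""
        maes = {True: [], False: []}
        for flips in (True, False):
            for seed in range(5):
                train = make_patch_cohort(
                    n_subjects=3, ages=(0, 5, 10, 15), n_bands=6, patch=8, seed=seed
                )
                val = make_patch_cohort(
                    n_subjects=2, ages=(2, 8, 14), n_bands=6, patch=8, seed=100 + seed
                )
                spec = CnnSpec(
                    cnn_config=CnnConfig(
                        n_bands=6,
                        spectral_channels=(3, 3, 3),
                        spatial_channels=(4, 4),
                        head_hidden=8,
                    ),
                    train_config=TrainConfig(
                        learning_rate=5e-3,
                        batch_size=4,
                        max_epochs=10,
                        patience=9,
                        augment_flips=flips,
                    ),
                )
                fitted = spec.fit(train, val, seed=seed)
                maes[flips].append(
                    float(np.mean(np.abs(fitted.predict(val) - val.ages())))
                )
        rng = np.random.default_rng(0)

        def boot_interval(values):
            values = np.asarray(values)
            means = [
                rng.choice(values, size=len(values), replace=True).mean() for _ in range(300)
            ]
            return np.percentile(means, [2.5, 97.5])

        lo_t, hi_t = boot_interval(maes[True])
        lo_f, hi_f = boot_interval(maes[False])
        assert lo_t <= hi_f and lo_f <= hi_t  # intervals overlap


class TestCheckpoint:
    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path):
        ds = make_patch_cohort(seed=5)
        spec = CnnSpec(
            cnn_config=CnnConfig(
                n_bands=6, spectral_channels=(3, 3, 3), spatial_channels=(4, 4), head_hidden=8
            ),
            train_config=TrainConfig(learning_rate=3e-3, batch_size=4, max_epochs=3, patience=2),
        )
        fitted = spec.fit(ds, ds, seed=0)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(fitted, path)
        loaded = load_checkpoint(path)
        np.testing.assert_allclose(loaded.predict(ds), fitted.predict(ds), rtol=1e-6)
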