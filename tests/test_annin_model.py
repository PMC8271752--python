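import numpy as np
import pytest

from annispec import annin_model as am
from annispec import evaluation as ev
from annispec.annin_model import (
    AnniNetConfig,
    AnniNetModel,
    FeatureMap,
    TrainConfig,
    rmse_reconstruction,
    rmse_regression,
    selu,
    softplus,
)
from annispec.preprocessing import AugmentSpec

SMALL = AnniNetConfig(k_filters=4, kernel_width=5, n_conv_blocks=2,
                      pool_factor=2, dense_widths=(16,), dropout_rate=0.1)


@pytest.fixture(scope="module")
def trained_small(single_analyte_dataset):
    model = AnniNetModel(SMALL, single_analyte_dataset.n_channels, 1, init_seed=0)
    model.fit(single_analyte_dataset, TrainConfig(epochs=30, batch_size=16, seed=0))
    return model


class TestActivations:
    def test_selu_zero(self):
        assert selu(0.0) == 0.0

    def test_selu_positive_branch(self):
        lam = am.SELU_LAMBDA
        for x in (0.5, 1.0, 7.3):
            assert selu(x) == pytest.approx(lam * x, abs=1e-15)

    def test_selu_negative_limit(self):
        assert selu(-50.0) == pytest.approx(-am.SELU_LAMBDA * am.SELU_ALPHA, abs=1e-12)

    def test_selu_custom_constants(self):
        assert selu(2.0, lam=2.0, alpha=1.0) == 4.0

    def test_softplus_ln2(self):
        assert softplus(0.0) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_softplus_positive(self):
        xs = np.array([-100.0, -1.0, 0.0, 1.0, 100.0])
        assert np.all(softplus(xs) > 0)

    def test_softplus_no_overflow(self):
        assert softplus(1000.0) == pytest.approx(1000.0, abs=1e-9)


class TestLossFormulas:
    def test_reconstruction_zero(self):
        x = np.arange(5.0)
        assert rmse_reconstruction(x, x) == 0.0

    def test_reconstruction_single_channel(self):
        assert rmse_reconstruction([2.0], [5.0]) == pytest.approx(3.0)

    def test_reconstruction_hand_case(self):
        # residual (3,4,0,0), Q=4 -> sqrt(25/4) = 2.5
        x_hat = np.array([3.0, 4.0, 0.0, 0.0])
        x = np.zeros(4)
        assert rmse_reconstruction(x_hat, x) == pytest.approx(2.5, abs=1e-12)

    def test_regression_hand_case(self):
        # residual (1,1,1,1), C=4 -> 1.0
        assert rmse_regression(np.ones(4), np.zeros(4)) == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse_reconstruction(np.zeros(3), np.zeros(4))


class TestConfig:
    def test_pooled_length(self):
        cfg = AnniNetConfig(n_conv_blocks=2, pool_factor=4)
        assert cfg.pooled_length(700) == 44  # ceil(ceil(700/4)/4)
        assert cfg.pooled_length(128) == 8

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            AnniNetConfig(kernel_width=4)
        with pytest.raises(ValueError):
            AnniNetConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            AnniNetConfig(pool_factor=1)

    def test_feature_map_type(self):
        fm = FeatureMap(np.zeros((8, 4)))
        assert fm.p == 8 and fm.k == 4
        with pytest.raises(ValueError):
            FeatureMap(np.zeros(8))


class TestEncode:
    def test_shape_contract(self, trained_small, single_analyte_dataset):
        maps = trained_small.encode(single_analyte_dataset.X[:5])
        p = SMALL.pooled_length(single_analyte_dataset.n_channels)
        assert maps.shape == (5, p, SMALL.k_filters)
        assert p < single_analyte_dataset.n_channels

    def test_zero_input_zero_map(self):
        model = AnniNetModel(SMALL, 64, 1, init_seed=1)
        model.x_mean, model.x_sd = 0.0, 1.0  # identity scaler
        maps = model.encode(np.zeros((2, 64)))
        np.testing.assert_allclose(maps, 0.0, atol=1e-12)

    def test_translation_equivariance(self):
        # one conv block: input rolled by pool_factor -> map rolled by 1
        cfg = AnniNetConfig(k_filters=3, kernel_width=5, n_conv_blocks=1,
                            pool_factor=4, dense_widths=(8,), dropout_rate=0.0)
        model = AnniNetModel(cfg, 64, 1, init_seed=2)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 64))
        m0 = model.encode(x)
        m1 = model.encode(np.roll(x, cfg.pool_factor, axis=1))
        np.testing.assert_allclose(m1[0, 2:-2], np.roll(m0[0], 1, axis=0)[2:-2],
                                   atol=1e-6)


class TestDecode:
    def test_shape_contract(self, trained_small, single_analyte_dataset):
        maps = trained_small.encode(single_analyte_dataset.X[:3])
        recon = trained_small.decode(maps)
        assert recon.shape == (3, single_analyte_dataset.n_channels)

    def test_zero_map_zero_reconstruction(self):
        model = AnniNetModel(SMALL, 64, 1, init_seed=3)
        model.x_mean, model.x_sd = 0.0, 1.0
        p = SMALL.pooled_length(64)
        recon = model.decode(np.zeros((2, p, SMALL.k_filters)))
        np.testing.assert_allclose(recon, 0.0, atol=1e-12)

    def test_trained_reconstruction_beats_data_sd(self, trained_small,
                                                  single_analyte_dataset):
        X = single_analyte_dataset.X
        recon = trained_small.reconstruct(X)
        err = np.sqrt(np.mean((recon - X) ** 2))
        assert err < X.std()


class TestRegress:
    def test_outputs_positive(self, trained_small, single_analyte_dataset):
        maps = trained_small.encode(single_analyte_dataset.X[:10])
        out = trained_small.regress(maps)
        assert out.shape == (10, 1)
        assert np.all(out > 0)

    def test_positive_even_for_random_maps(self):
        model = AnniNetModel(SMALL, 64, 3, init_seed=4)
        p = SMALL.pooled_length(64)
        maps = np.random.default_rng(1).normal(size=(7, p, SMALL.k_filters)) * 10
        out = model.regress(maps)
        assert out.shape == (7, 3)
        assert np.all(out > 0)

    def test_prior_requirements(self):
        cfg = AnniNetConfig(k_filters=2, kernel_width=3, n_conv_blocks=1,
                            pool_factor=4, dense_widths=(4,), prior_dim=1)
        model = AnniNetModel(cfg, 32, 1, init_seed=5)
        maps = np.zeros((2, cfg.pooled_length(32), 2))
        with pytest.raises(ValueError, match="requires a prior"):
            model.regress(maps)
        model.regress(maps, prior=np.array([20.0, 30.0]))  # ok
        noprior = AnniNetModel(SMALL, 64, 1, init_seed=5)
        with pytest.raises(ValueError, match="prior_dim=0"):
            noprior.regress(np.zeros((1, SMALL.pooled_length(64), 4)),
                            prior=np.array([1.0]))

    def test_prior_changes_predictions(self, two_analyte_dataset):
        cfg = AnniNetConfig(k_filters=4, kernel_width=5, n_conv_blocks=2,
                            pool_factor=2, dense_widths=(16,), dropout_rate=0.0,
                            prior_dim=1)
        model = AnniNetModel(cfg, two_analyte_dataset.n_channels, 2, init_seed=6)
        model.fit(two_analyte_dataset, TrainConfig(epochs=25, seed=0))
        X = two_analyte_dataset.X[:4]
        cold = model.predict(X, prior=np.full(4, 20.0))
        warm = model.predict(X, prior=np.full(4, 30.0))
        assert not np.allclose(cold, warm)


class TestTrain:
    def test_smoke_two_epochs(self, single_analyte_dataset):
        model = AnniNetModel(SMALL, single_analyte_dataset.n_channels, 1, init_seed=7)
        ds = single_analyte_dataset.subset(range(16))
        model.fit(ds, TrainConfig(epochs=2, seed=0))
        assert len(model.training_history) == 2
        for rec in model.training_history:
            assert {"epoch", "loss", "recon_rmse", "regr_rmse"} <= set(rec)

    def test_loss_decreases(self, trained_small):
        h = trained_small.training_history
        assert h[-1]["loss"] < h[0]["loss"]
        assert h[-1]["recon_rmse"] < h[0]["recon_rmse"]

    def test_zero_recon_weight_freezes_decoder(self, single_analyte_dataset):
        model = AnniNetModel(SMALL, single_analyte_dataset.n_channels, 1, init_seed=8)
        before = [p.value.copy() for p in model.decoder_parameters()]
        model.fit(single_analyte_dataset.subset(range(16)),
                  TrainConfig(epochs=3, seed=0, loss_weights=(0.0, 1.0)))
        after = model.decoder_parameters()
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a.value)
        assert all(rec["recon_rmse"] == 0.0 for rec in model.training_history)

    def test_determinism(self, single_analyte_dataset):
        ds = single_analyte_dataset.subset(range(24))
        cfg = TrainConfig(epochs=4, seed=11,
                          augment=AugmentSpec(baseline_coeff_sd=0.01, seed=11))
        h = []
        for _ in range(2):
            model = AnniNetModel(SMALL, ds.n_channels, 1, init_seed=11)
            model.fit(ds, cfg)
            h.append([rec["loss"] for rec in model.training_history])
        assert h[0] == h[1]

    def test_requires_targets(self, single_analyte_dataset):
        from annispec.spectra_core import SpectralDataset
        ds = SpectralDataset(X=single_analyte_dataset.X,
                             grid=single_analyte_dataset.grid)
        model = AnniNetModel(SMALL, ds.n_channels, 1, init_seed=9)
        with pytest.raises(ValueError, match="targets"):
            model.fit(ds, TrainConfig(epochs=1))


class TestPredict:
    def test_deterministic(self, trained_small, single_analyte_dataset):
        X = single_analyte_dataset.X[:6]
        np.testing.assert_array_equal(trained_small.predict(X),
                                      trained_small.predict(X))

    def test_raw_spectra_accepted(self, trained_small, single_analyte_dataset):
        # no SNV or other preprocessing required before predict
        pred = trained_small.predict(single_analyte_dataset.X)
        assert pred.shape == (single_analyte_dataset.n_samples, 1)

    def test_unfitted_raises(self):
        model = AnniNetModel(SMALL, 64, 1, init_seed=10)
        with pytest.raises(RuntimeError, match="not fitted"):
            model.predict(np.zeros((1, 64)))

    def test_equals_regress_encode_up_to_affine(self, trained_small,
                                                single_analyte_dataset):
        X = single_analyte_dataset.X[:5]
        raw = trained_small.regress(trained_small.encode(X))
        np.testing.assert_allclose(trained_small.predict(X),
                                   trained_small._unscale_y(raw), atol=1e-12)


class TestPersistence:
    def test_save_load_round_trip(self, trained_small, single_analyte_dataset,
                                  tmp_path):
        trained_small.save(tmp_path / "model")
        loaded = AnniNetModel.load(tmp_path / "model")
        X = single_analyte_dataset.X[:4]
        np.testing.assert_allclose(loaded.predict(X), trained_small.predict(X),
                                   atol=1e-12)
        assert len(loaded.training_history) == len(trained_small.training_history)
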