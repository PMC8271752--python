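import numpy as np
import pandas as pd
import pytest

from annispec import annin_model as am
from annispec import evaluation as ev
from annispec import synthetic_data as sd
from annispec.evaluation import (
    AnniNetAdapter,
    ConstantAdapter,
    ExperimentReport,
    LSSVRAdapter,
    PLSRAdapter,
    attribution_map,
    concat_datasets,
    r2_score,
    rmse,
    run_shift_robustness,
    run_temperature_experiment,
    run_transfer_experiment,
    shift_ratio,
    split_train_test,
)
from annispec.spectra_core import SpectralDataset, WavelengthGrid


class TestRMSE:
    def test_perfect(self):
        y = np.arange(5.0)
        assert rmse(y, y) == 0.0

    def test_hand_case(self):
        # residuals (3, 4), N=2 -> sqrt(25/2)
        assert rmse(np.array([3.0, 4.0]), np.zeros(2)) == \
            pytest.approx(np.sqrt(12.5), abs=1e-12)

    def test_reorder_invariant(self):
        rng = np.random.default_rng(0)
        y, yh = rng.normal(size=20), rng.normal(size=20)
        perm = rng.permutation(20)
        assert rmse(yh, y) == pytest.approx(rmse(yh[perm], y[perm]), abs=1e-12)

    def test_per_column(self):
        y = np.zeros((2, 2))
        yh = np.array([[3.0, 0.0], [4.0, 0.0]])
        np.testing.assert_allclose(rmse(yh, y), [np.sqrt(12.5), 0.0])


class TestR2:
    def test_perfect(self):
        y = np.arange(5.0)
        assert r2_score(y, y) == 1.0

    def test_mean_predictor_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yh = np.full(4, y.mean())
        assert r2_score(yh, y) == pytest.approx(0.0, abs=1e-12)

    def test_worse_than_mean_negative(self):
        y = np.array([1.0, 2.0, 3.0])
        yh = np.array([10.0, -5.0, 7.0])
        assert r2_score(yh, y) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r2_score(np.zeros(3), np.full(3, 2.0))


class TestSplit:
    def test_sizes_60_75pct(self):
        grid = WavelengthGrid.uniform(1100.0, 1108.0, 2.0)
        ds = SpectralDataset(X=np.random.default_rng(0).normal(size=(60, 5)),
                             grid=grid)
        tr, te = split_train_test(ds, 0.75, seed=1)
        assert tr.n_samples == 45 and te.n_samples == 15

    def test_disjoint_exhaustive(self, small_dataset):
        tr, te = split_train_test(small_dataset, 0.5, seed=2)
        ids = set(tr.sample_ids) | set(te.sample_ids)
        assert ids == set(small_dataset.sample_ids)
        assert not set(tr.sample_ids) & set(te.sample_ids)

    def test_seed_reproducible(self, small_dataset):
        a = split_train_test(small_dataset, 0.5, seed=3)
        b = split_train_test(small_dataset, 0.5, seed=3)
        assert a[0].sample_ids == b[0].sample_ids

    def test_degenerate_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            split_train_test(small_dataset, 0.01, seed=0)


class TestReport:
    def test_serialization_round_trip(self, tmp_path):
        df = pd.DataFrame([{"model": "m", "condition": "c", "target": "t",
                            "rmse": 1.5, "r2": 0.9}])
        rep = ExperimentReport(df, metadata={"seed": 0})
        rep.to_csv(tmp_path / "r.csv")
        loaded = ExperimentReport.from_csv(tmp_path / "r.csv")
        pd.testing.assert_frame_equal(loaded.df, rep.df)
        assert loaded.metadata == rep.metadata

    def test_negative_rmse_rejected(self):
        df = pd.DataFrame([{"model": "m", "target": "t", "rmse": -1.0, "r2": 0.5}])
        with pytest.raises(ValueError):
            ExperimentReport(df)

    def test_render_smoke(self):
        df = pd.DataFrame([{"model": "m", "target": "t", "rmse": 1.0, "r2": 0.5}])
        assert "m" in ExperimentReport(df).render()


@pytest.fixture(scope="module")
def paired_instruments():
    grid = WavelengthGrid.uniform(1100.0, 1226.0, 2.0)
    analyte = sd.AnalyteSpec("a", (sd.AbsorptionBand(1160.0, 10.0, 0.01),),
                             (1.0, 10.0))
    cfg = sd.SimulationConfig(analytes=(analyte,), n_samples=30, seed=1)
    instruments = [sd.InstrumentSpec(grid, label=lab) for lab in ("i1", "i2", "i3")]
    return sd.simulate_paired(cfg, instruments)


class TestTransferExperiment:
    def test_identical_instruments_equal_rmse(self, paired_instruments):
        models = [PLSRAdapter(n_components=3)]
        rep = run_transfer_experiment(models, paired_instruments, n_train=20, seed=0)
        df = rep.df
        # noiseless identical instruments: child RMSE equals parent RMSE
        for parent in ("i1", "i2", "i3"):
            block = df[(df.parent == parent)]
            assert block.rmse.max() - block.rmse.min() < 1e-10

    def test_report_layout(self, paired_instruments):
        models = [PLSRAdapter(n_components=3), ConstantAdapter()]
        rep = run_transfer_experiment(models, paired_instruments, n_train=20, seed=0)
        assert len(rep.df) == 2 * 3 * 3  # models x parents x children (1 target)

    def test_shared_split_across_models(self, paired_instruments):
        # constant model's per-parent RMSE must be identical across runs,
        # proving the split only depends on (seed, parent)
        a = run_transfer_experiment([ConstantAdapter()], paired_instruments,
                                    n_train=20, seed=5)
        b = run_transfer_experiment([ConstantAdapter(), PLSRAdapter(n_components=2)],
                                    paired_instruments, n_train=20, seed=5)
        ca = a.df[a.df.model == "constant"].rmse.to_numpy()
        cb = b.df[b.df.model == "constant"].rmse.to_numpy()
        np.testing.assert_array_equal(ca, cb)

    def test_unpaired_rejected(self, paired_instruments):
        bad = dict(paired_instruments)
        first = next(iter(bad))
        bad[first] = bad[first].subset(range(10))
        with pytest.raises(ValueError, match="unpaired"):
            run_transfer_experiment([ConstantAdapter()], bad, n_train=5, seed=0)

    def test_n_train_bound(self, paired_instruments):
        with pytest.raises(ValueError):
            run_transfer_experiment([ConstantAdapter()], paired_instruments,
                                    n_train=30, seed=0)


class TestShiftRobustness:
    def test_constant_model_ratio_one(self, single_analyte_dataset):
        rep = run_shift_robustness([ConstantAdapter()], single_analyte_dataset,
                                   seed=0)
        ratios = shift_ratio(rep)
        np.testing.assert_allclose(ratios["ratio"], 1.0, atol=1e-12)

    def test_schema_contains_both_conditions(self, single_analyte_dataset):
        rep = run_shift_robustness([ConstantAdapter(), PLSRAdapter(n_components=2)],
                                   single_analyte_dataset, seed=0)
        assert set(rep.df.condition) == {"unshifted", "shifted"}
        assert set(rep.df.model) == {"constant", "plsr"}


@pytest.fixture(scope="module")
def series():
    grid = WavelengthGrid.uniform(1100.0, 1226.0, 2.0)
    analyte = sd.AnalyteSpec(
        "a", (sd.AbsorptionBand(1160.0, 10.0, 0.01,
                                temp_center_shift_nm_per_C=0.1),), (1.0, 10.0))
    out = {}
    for temp, label in ((20.0, "20C"), (30.0, "30C")):
        cfg = sd.SimulationConfig(analytes=(analyte,), n_samples=24,
                                  temperature_range_C=(temp, temp), seed=4)
        out[label] = sd.simulate_dataset(
            cfg, sd.InstrumentSpec(grid, label="t"))
    return out


class TestTemperatureExperiment:
    def test_report_layout_with_noprior_row(self, series):
        annin = AnniNetAdapter(
            am.AnniNetConfig(k_filters=4, kernel_width=5, n_conv_blocks=2,
                             pool_factor=2, dense_widths=(8,), dropout_rate=0.0,
                             prior_dim=1),
            am.TrainConfig(epochs=8, seed=0))
        rep = run_temperature_experiment([annin, ConstantAdapter()],
                                         series["20C"], series["30C"], seed=0)
        df = rep.df
        assert set(df.condition) == {"20C", "30C", "20C+30C"}
        assert "annin_noprior" in set(df.model)
        noprior = df[df.model == "annin_noprior"]
        assert set(noprior.condition) == {"20C+30C"}

    def test_prior_changes_pooled_predictions(self, series):
        annin = AnniNetAdapter(
            am.AnniNetConfig(k_filters=4, kernel_width=5, n_conv_blocks=2,
                             pool_factor=2, dense_widths=(8,), dropout_rate=0.0,
                             prior_dim=1),
            am.TrainConfig(epochs=20, seed=0))
        pooled = concat_datasets([series["20C"], series["30C"]], ["a_", "b_"])
        annin.fit(pooled)
        with_prior = annin.predict(pooled)
        nop = annin.without_prior()
        nop.fit(pooled)
        without = nop.predict(pooled)
        assert not np.allclose(with_prior, without)

    def test_incompatible_series_rejected(self, series, small_dataset):
        with pytest.raises(ValueError):
            run_temperature_experiment([ConstantAdapter()], series["20C"],
                                       small_dataset, seed=0)


class TestAttributionMap:
    def test_identity_policy_zero(self, single_analyte_dataset):
        model = ConstantAdapter().fit(single_analyte_dataset)
        amap = attribution_map(model, single_analyte_dataset, window_width=8,
                               stride=4, mask_value_policy="identity")
        np.testing.assert_allclose(amap.values, 0.0, atol=1e-15)

    def test_constant_model_zero_any_policy(self, single_analyte_dataset):
        model = ConstantAdapter().fit(single_analyte_dataset)
        for policy in ("interp", "zero", "mean"):
            amap = attribution_map(model, single_analyte_dataset, window_width=8,
                                   stride=8, mask_value_policy=policy)
            np.testing.assert_allclose(amap.values, 0.0, atol=1e-15)

    def test_windows_cover_spectrum(self, single_analyte_dataset):
        model = ConstantAdapter().fit(single_analyte_dataset)
        amap = attribution_map(model, single_analyte_dataset, window_width=10,
                               stride=7)
        q = single_analyte_dataset.n_channels
        covered = np.zeros(q, dtype=bool)
        for s in amap.window_starts:
            covered[s:s + amap.window_width] = True
        assert covered.all()

    def test_window_too_wide(self, single_analyte_dataset):
        model = ConstantAdapter().fit(single_analyte_dataset)
        with pytest.raises(ValueError):
            attribution_map(model, single_analyte_dataset,
                            window_width=single_analyte_dataset.n_channels + 1)

    def test_localizes_planted_band(self, single_analyte_dataset):
        # band planted at 1160 nm (channel 30) on a 1100-1226 nm grid
        tr, te = split_train_test(single_analyte_dataset, 0.75, seed=0)
        annin = AnniNetAdapter(
            am.AnniNetConfig(k_filters=4, kernel_width=5, n_conv_blocks=2,
                             pool_factor=2, dense_widths=(16,), dropout_rate=0.1),
            am.TrainConfig(epochs=60, seed=0))
        annin.fit(tr)
        amap = attribution_map(annin, te, window_width=8, stride=4)
        s, e = amap.peak_window("a")
        wl = te.grid.wavelengths_nm
        assert wl[s] <= 1160.0 <= wl[e - 1]
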