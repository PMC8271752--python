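import numpy as np
import pytest

from annispec.spectra_core import SpectralDataset, WavelengthGrid
from annispec import synthetic_data as sd


@pytest.fixture
def small_grid():
    return WavelengthGrid.uniform(1100.0, 1108.0, 2.0)  # 5 channels


@pytest.fixture
def small_dataset(small_grid):
    rng = np.random.default_rng(42)
    return SpectralDataset(
        X=rng.uniform(0.1, 0.9, size=(3, 5)),
        grid=small_grid,
        Y=rng.uniform(1.0, 5.0, size=(3, 2)),
        target_names=("glucose", "fructose"),
        target_units=("g/L", "g/L"),
        sample_ids=("a", "b", "c"),
        aux={"temperature_C": np.array([20.0, 25.0, 30.0])},
    )


@pytest.fixture(scope="session")
def single_analyte_dataset():
    """Noiseless-ish single-band mixture on a 64-channel grid (fast)."""
    grid = WavelengthGrid.uniform(1100.0, 1226.0, 2.0)
    analyte = sd.AnalyteSpec(
        "a", (sd.AbsorptionBand(1160.0, 10.0, 0.01),), (1.0, 10.0))
    cfg = sd.SimulationConfig(analytes=(analyte,), n_samples=64, seed=7)
    return sd.simulate_dataset(cfg, sd.InstrumentSpec(grid, label="unit"))


@pytest.fixture(scope="session")
def two_analyte_dataset():
    grid = WavelengthGrid.uniform(1100.0, 1226.0, 2.0)
    analytes = (
        sd.AnalyteSpec("a", (sd.AbsorptionBand(1140.0, 10.0, 0.01),
                             sd.AbsorptionBand(1190.0, 14.0, 0.006)), (1.0, 10.0)),
        sd.AnalyteSpec("b", (sd.AbsorptionBand(1170.0, 12.0, 0.008),
                             sd.AbsorptionBand(1210.0, 10.0, 0.005)), (0.5, 5.0)),
    )
    cfg = sd.SimulationConfig(analytes=analytes, n_samples=48, seed=3,
                              temperature_range_C=(20.0, 30.0))
    return sd.simulate_dataset(cfg, sd.InstrumentSpec(grid, noise_sd=1e-4, label="unit"))
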