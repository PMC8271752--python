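"""Synthetic Beer-Lambert mixture spectra with instrument and temperature effects.

Clean absorbance for a sample is a linear combination of Gaussian-band
analyte absorptivities (scaled by concentration and optical path length)
plus a random low-order polynomial baseline. Band centers and widths drift
with sample temperature; a virtual instrument then applies a wavelength
offset, gain, additive offset, and Gaussian noise.

Presets emulate three benchmark designs: a corn-like instrument-transfer
set (80 samples, 700 channels, three instruments), an alcohol-mixture-like
set (fraction targets on the simplex, temperatures 30-70 C), and a
grape-must-like set (four constituents, 1100-1350 nm, series at 20/30 C).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .spectra_core import SpectralDataset, WavelengthGrid

__all__ = [
    "AbsorptionBand",
    "AnalyteSpec",
    "InstrumentSpec",
    "SimulationConfig",
    "absorptivity",
    "simulate_dataset",
    "simulate_paired",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class AbsorptionBand:
    """One Gaussian absorption band with linear temperature response.

    ``amplitude`` is absorbance per concentration unit per mm path at the
    band center. At temperature offset dT from the reference, the center
    moves by ``temp_center_shift_nm_per_C * dT`` and the width scales by
    ``1 + temp_width_scale_per_C * dT``.
    """

    center_nm: float
    width_nm: float
    amplitude: float
    temp_center_shift_nm_per_C: float = 0.0
    temp_width_scale_per_C: float = 0.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class AnalyteSpec:
    """Named constituent: a set of absorption bands and a concentration range."""

    name: str
    bands: tuple
    concentration_range: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if not self.bands:
            raise ValueError("analyte needs at least one band")
        lo, hi = self.concentration_range
        if not (0 <= lo < hi):
            raise ValueError("concentration range must satisfy 0 <= lo < hi")


@dataclass(frozen=True)
class InstrumentSpec:
    """Virtual instrument: grid plus response distortions."""

    grid: WavelengthGrid
    wavelength_offset_nm: float = 0.0
    gain: float = 1.0
    additive_offset: float = 0.0
    noise_sd: float = 0.0
    label: str = "instrument"

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings: analyte library, path length, baseline, temperatures."""

    analytes: tuple
    path_length_mm: float = 10.0
    baseline_poly_degree: int = 2
    baseline_coeff_sd: float = 0.0
    reference_temperature_C: float = 25.0
    temperature_range_C: tuple = (25.0, 25.0)
    n_samples: int = 1
    seed: int = 0
    simplex_targets: bool = False  # draw concentrations from a flat simplex

    def __post_init__(self) -> None:
        object.__setattr__(self, "analytes", tuple(self.analytes))
        if not self.analytes:
            raise ValueError("need at least one analyte")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.path_length_mm <= 0:
            raise ValueError("path_length_mm must be > 0")
        if self.baseline_coeff_sd < 0:
            raise ValueError("baseline_coeff_sd must be >= 0")
        lo, hi = self.temperature_range_C
        if lo > hi:
            raise ValueError("temperature range lo must be <= hi")


def absorptivity(analyte: AnalyteSpec, grid: WavelengthGrid, temperature_C: float,
                 ref_temperature_C: float) -> np.ndarray:
    """Per-channel absorptivity of an analyte at the given temperature.

    Sum over bands of Gaussian profiles with temperature-adjusted center
    and width; always nonnegative.
    """
    wl = grid.wavelengths_nm
    dT = temperature_C - ref_temperature_C
    eps = np.zeros_like(wl)
    for band in analyte.bands:
        center = band.center_nm + band.temp_center_shift_nm_per_C * dT
        width = band.width_nm * (1.0 + band.temp_width_scale_per_C * dT)
        if width <= 0:
            raise ValueError(
                f"band width became non-positive at dT={dT:+.1f} C "
                f"(band at {band.center_nm} nm)")
        eps += band.amplitude * np.exp(-((wl - center) ** 2) / (2.0 * width ** 2))
    return eps


def _draw_concentrations(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n, c = cfg.n_samples, len(cfg.analytes)
    if cfg.simplex_targets:
        return rng.dirichlet(np.ones(c), size=n)
    conc = np.empty((n, c))
    for j, analyte in enumerate(cfg.analytes):
        lo, hi = analyte.concentration_range
        conc[:, j] = rng.uniform(lo, hi, size=n)
    return conc


def _clean_absorbance(cfg: SimulationConfig, grid_nm: np.ndarray,
                      conc: np.ndarray, temps: np.ndarray) -> np.ndarray:
    """Beer-Lambert mixture absorbance on the given wavelength values."""
    fake_grid = WavelengthGrid(grid_nm)
    n = conc.shape[0]
    A = np.zeros((n, grid_nm.size))
    for i in range(n):
        for j, analyte in enumerate(cfg.analytes):
            eps = absorptivity(analyte, fake_grid, temps[i], cfg.reference_temperature_C)
            A[i] += conc[i, j] * eps * cfg.path_length_mm
    return A


def _apply_instrument(cfg: SimulationConfig, instrument: InstrumentSpec,
                      conc: np.ndarray, temps: np.ndarray,
                      baselines: np.ndarray, noise_rng: np.random.Generator,
                      sample_ids: tuple) -> SpectralDataset:
    wl = instrument.grid.wavelengths_nm
    # the instrument reports channel wavelength wl but actually samples
    # the scene at wl + offset: evaluate the continuous model there
    A = _clean_absorbance(cfg, wl + instrument.wavelength_offset_nm, conc, temps)
    if cfg.baseline_coeff_sd > 0:
        t = (wl - wl[0]) / (wl[-1] - wl[0])
        A = A + np.polynomial.polynomial.polyval(t, baselines.T)
    A = instrument.gain * A + instrument.additive_offset
    if instrument.noise_sd > 0:
        A = A + noise_rng.normal(0.0, instrument.noise_sd, size=A.shape)
    names = tuple(a.name for a in cfg.analytes)
    units = tuple("fraction" if cfg.simplex_targets else "g/L" for _ in names)
    return SpectralDataset(
        X=A, grid=instrument.grid, Y=conc.copy(), target_names=names,
        target_units=units, sample_ids=sample_ids,
        aux={"temperature_C": temps.copy()}, instrument_id=instrument.label,
    )


def _instrument_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode("utf-8"))])


def simulate_dataset(cfg: SimulationConfig, instrument: InstrumentSpec) -> SpectralDataset:
    """Generate one dataset: draw concentrations/temperatures, apply instrument.

    Identical ``cfg.seed`` yields byte-identical output; noise is drawn
    from a per-instrument stream so paired instruments get independent
    noise.
    """
    rng = np.random.default_rng(cfg.seed)
    conc = _draw_concentrations(cfg, rng)
    lo, hi = cfg.temperature_range_C
    temps = rng.uniform(lo, hi, size=cfg.n_samples) if hi > lo else np.full(cfg.n_samples, lo)
    baselines = rng.normal(0.0, 1.0, size=(cfg.n_samples, cfg.baseline_poly_degree + 1))
    baselines *= cfg.baseline_coeff_sd
    ids = tuple(f"s{i:04d}" for i in range(cfg.n_samples))
    noise_rng = _instrument_rng(cfg.seed, instrument.label)
    return _apply_instrument(cfg, instrument, conc, temps, baselines, noise_rng, ids)


def simulate_paired(cfg: SimulationConfig, instruments) -> dict:
    """Measure the *same* samples on several instruments (paired design)."""
    rng = np.random.default_rng(cfg.seed)
    conc = _draw_concentrations(cfg, rng)
    lo, hi = cfg.temperature_range_C
    temps = rng.uniform(lo, hi, size=cfg.n_samples) if hi > lo else np.full(cfg.n_samples, lo)
    baselines = rng.normal(0.0, 1.0, size=(cfg.n_samples, cfg.baseline_poly_degree + 1))
    baselines *= cfg.baseline_coeff_sd
    ids = tuple(f"s{i:04d}" for i in range(cfg.n_samples))
    out = {}
    for inst in instruments:
        noise_rng = _instrument_rng(cfg.seed, inst.label)
        out[inst.label] = _apply_instrument(cfg, inst, conc, temps, baselines, noise_rng, ids)
    return out


# --------------------------------------------------------------------------
# preset band libraries
#
# Bands deliberately overlap within each library so that no single channel
# identifies one constituent and multivariate calibration is required.

def _corn_analytes() -> tuple:
    return (
        AnalyteSpec("moisture", bands=(
            AbsorptionBand(1410.0, 30.0, 0.020, temp_center_shift_nm_per_C=0.15),
            AbsorptionBand(1930.0, 40.0, 0.035, temp_center_shift_nm_per_C=0.20),
        ), concentration_range=(9.0, 11.0)),
        AnalyteSpec("oil", bands=(
            AbsorptionBand(1210.0, 25.0, 0.010),
            AbsorptionBand(1725.0, 20.0, 0.014),
            AbsorptionBand(2310.0, 25.0, 0.016),
        ), concentration_range=(3.0, 4.0)),
        AnalyteSpec("protein", bands=(
            AbsorptionBand(1510.0, 35.0, 0.008),
            AbsorptionBand(2050.0, 45.0, 0.012),
            AbsorptionBand(2180.0, 35.0, 0.010),
        ), concentration_range=(7.5, 9.8)),
        AnalyteSpec("starch", bands=(
            AbsorptionBand(1450.0, 50.0, 0.006),
            AbsorptionBand(2100.0, 60.0, 0.009),
            AbsorptionBand(1580.0, 40.0, 0.005),
        ), concentration_range=(62.0, 66.0)),
    )


def _mixture_analytes() -> tuple:
    # fraction targets; amplitudes per unit fraction, narrow CH/OH overtones
    return (
        AnalyteSpec("ethanol", bands=(
            AbsorptionBand(1190.0, 7.2, 0.055),
            AbsorptionBand(1395.0, 8.8, 0.045, temp_center_shift_nm_per_C=0.01),
            AbsorptionBand(1580.0, 11.2, 0.030),
        ), concentration_range=(0.0, 1.0)),
        AnalyteSpec("isopropanol", bands=(
            AbsorptionBand(1170.0, 6.4, 0.060),
            AbsorptionBand(1378.0, 8.0, 0.050, temp_center_shift_nm_per_C=0.008),
            AbsorptionBand(1540.0, 10.4, 0.028),
        ), concentration_range=(0.0, 1.0)),
        AnalyteSpec("water", bands=(
            AbsorptionBand(1450.0, 28.0, 0.080, temp_center_shift_nm_per_C=0.02,
                           temp_width_scale_per_C=0.001),
            AbsorptionBand(1200.0, 35.0, 0.020, temp_center_shift_nm_per_C=0.01),
        ), concentration_range=(0.0, 1.0)),
    )


def _grape_analytes(variety: str) -> tuple:
    # concentration ranges per variety (g/L); acids absorb mainly below
    # 1160 nm, sugars add structure near 1300-1350 nm
    ranges = {
        "dornfelder": {"malic_acid": (0.88, 3.31), "tartaric_acid": (3.15, 4.48),
                       "fructose": (42.14, 93.46), "glucose": (49.35, 106.42)},
        "pinot_noir": {"malic_acid": (2.11, 5.89), "tartaric_acid": (2.95, 6.68),
                       "fructose": (66.51, 135.55), "glucose": (82.99, 114.17)},
    }[variety]
    return (
        AnalyteSpec("malic_acid", bands=(
            AbsorptionBand(1128.0, 10.0, 0.0030),
            AbsorptionBand(1250.0, 18.0, 0.0008),
        ), concentration_range=ranges["malic_acid"]),
        AnalyteSpec("tartaric_acid", bands=(
            AbsorptionBand(1145.0, 11.0, 0.0028),
            AbsorptionBand(1262.0, 16.0, 0.0007),
        ), concentration_range=ranges["tartaric_acid"]),
        AnalyteSpec("fructose", bands=(
            AbsorptionBand(1318.0, 14.0, 0.00055),
            AbsorptionBand(1210.0, 20.0, 0.00025),
            AbsorptionBand(1150.0, 25.0, 0.00012),
        ), concentration_range=ranges["fructose"]),
        AnalyteSpec("glucose", bands=(
            AbsorptionBand(1340.0, 13.0, 0.00050),
            AbsorptionBand(1228.0, 19.0, 0.00028),
            AbsorptionBand(1165.0, 24.0, 0.00010),
        ), concentration_range=ranges["glucose"]),
    )


PRESET_NAMES = ("corn_like", "mixture_like", "grape_like")


def preset(name: str, seed: int = 0):
    """Built-in benchmark-like datasets.

    corn_like
        dict of three paired 80 x 700 instrument datasets ("m5", "mp5",
        "mp6"); mp5 and mp6 are nearly identical, m5 differs more.
    mixture_like
        one 200 x 256 dataset with three fraction targets on the unit
        simplex and temperatures uniform in 30-70 C.
    grape_like
        dict of two paired 60-sample series ("20C", "30C") on a
        1100-1350 nm grid with four g/L targets drawn per variety.
    """
    if name == "corn_like":
        grid = WavelengthGrid.uniform(1100.0, 2498.0, 2.0)  # Q = 700
        cfg = SimulationConfig(
            analytes=_corn_analytes(), path_length_mm=1.0,
            baseline_poly_degree=1, baseline_coeff_sd=0.004,
            reference_temperature_C=25.0, temperature_range_C=(25.0, 25.0),
            n_samples=80, seed=seed)
        instruments = (
            InstrumentSpec(grid, wavelength_offset_nm=3.0, gain=1.04,
                           additive_offset=0.015, noise_sd=4e-4, label="m5"),
            InstrumentSpec(grid, wavelength_offset_nm=0.0, gain=1.0,
                           additive_offset=0.0, noise_sd=3e-4, label="mp5"),
            InstrumentSpec(grid, wavelength_offset_nm=0.2, gain=1.005,
                           additive_offset=0.001, noise_sd=3e-4, label="mp6"),
        )
        return simulate_paired(cfg, instruments)
    if name == "mixture_like":
        grid = WavelengthGrid.uniform(1100.0, 1610.0, 2.0)  # Q = 256
        cfg = SimulationConfig(
            analytes=_mixture_analytes(), path_length_mm=10.0,
            baseline_poly_degree=1, baseline_coeff_sd=0.001,
            reference_temperature_C=50.0, temperature_range_C=(30.0, 70.0),
            n_samples=200, seed=seed, simplex_targets=True)
        inst = InstrumentSpec(grid, noise_sd=1e-4, label="mixture")
        return simulate_dataset(cfg, inst)
    if name == "grape_like":
        grid = WavelengthGrid.uniform(1100.0, 1350.0, 2.0)  # Q = 126
        rng = np.random.default_rng([seed, 0x67726170])
        sub_seeds = rng.integers(0, 2**31 - 1, size=2)
        series: dict = {}
        for temp, label in ((20.0, "20C"), (30.0, "30C")):
            parts = []
            for variety, n, sub_seed in (("dornfelder", 28, sub_seeds[0]),
                                         ("pinot_noir", 32, sub_seeds[1])):
                cfg = SimulationConfig(
                    analytes=_grape_analytes(variety), path_length_mm=10.0,
                    baseline_poly_degree=1, baseline_coeff_sd=0.002,
                    reference_temperature_C=25.0,
                    temperature_range_C=(temp, temp),
                    n_samples=n, seed=int(sub_seed))
                inst = InstrumentSpec(grid, noise_sd=3e-4, label="nirone")
                parts.append((variety, simulate_dataset(cfg, inst)))
            X = np.vstack([ds.X for _, ds in parts])
            Y = np.vstack([ds.Y for _, ds in parts])
            temps = np.concatenate([ds.temperatures for _, ds in parts])
            ids = tuple(f"{v}_{sid}" for v, ds in parts for sid in ds.sample_ids)
            series[label] = SpectralDataset(
                X=X, grid=grid, Y=Y,
                target_names=parts[0][1].target_names,
                target_units=parts[0][1].target_units,
                sample_ids=ids, aux={"temperature_C": temps},
                instrument_id="nirone")
        return series
    raise ValueError(f"unknown preset '{name}' (expected one of {PRESET_NAMES})")
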