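"""Spectral pre-treatments and training-time augmentations.

Classical chemometric pre-treatments (SNV, Savitzky-Golay smoothing and
derivatives) are used by the linear/kernel baselines; wavelength-shift and
baseline augmentations are used when training the neural network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import yaml
from scipy.signal import savgol_filter

from .spectra_core import SpectralDataset

__all__ = [
    "PreprocessSpec",
    "AugmentSpec",
    "snv",
    "savgol",
    "norris_derivative",
    "mean_center",
    "apply_pipeline",
    "augment_shift",
    "augment_baseline",
    "shift_one_band",
    "make_augmenter",
]


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum center and scale to unit sd.

    Uses the sample standard deviation (ddof=1). Raises on a constant
    spectrum.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("snv needs a 1-D spectrum of length >= 2")
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("zero variance spectrum")
    return (x - x.mean()) / sd


def savgol(spectrum: np.ndarray, window: int, polyorder: int, deriv: int = 0,
           spacing: float = 1.0) -> np.ndarray:
    """Savitzky-Golay local least-squares polynomial filter.

    Derivatives are scaled by ``spacing**deriv`` so units are per-nm when
    the grid spacing is passed. Mirror padding keeps the output length
    equal to the input length.
    """
    x = np.asarray(spectrum, dtype=float)
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    if x.shape[-1] < window:
        raise ValueError("spectrum shorter than window")
    return savgol_filter(x, window, polyorder, deriv=deriv, delta=spacing,
                         mode="mirror", axis=-1)


def norris_derivative(spectrum: np.ndarray, gap: int = 1, spacing: float = 1.0) -> np.ndarray:
    """Gap-segment first derivative (central difference over ``gap`` channels).

    Provided as an optional classical alternative to the Savitzky-Golay
    derivative; not part of any default pipeline. Edges are extended by
    the nearest interior derivative value.
    """
    x = np.asarray(spectrum, dtype=float)
    if gap < 1:
        raise ValueError("gap must be >= 1")
    if x.size < 2 * gap + 1:
        raise ValueError("spectrum too short for gap")
    d = np.empty_like(x)
    d[gap:-gap] = (x[2 * gap:] - x[:-2 * gap]) / (2 * gap * spacing)
    d[:gap] = d[gap]
    d[-gap:] = d[-gap - 1]
    return d


def mean_center(spectrum: np.ndarray) -> np.ndarray:
    x = np.asarray(spectrum, dtype=float)
    return x - x.mean()


@dataclass(frozen=True)
class PreprocessSpec:
    """Ordered pre-treatment pipeline.

    ``steps`` is a list of either the strings ``"snv"`` / ``"mean_center"``
    or tuples ``("savgol", {"window": 7, "polyorder": 2, "deriv": 1})``.
    """

    steps: tuple = ()

    def __post_init__(self) -> None:
        normalized = []
        for step in self.steps:
            if isinstance(step, str):
                if step not in ("snv", "mean_center"):
                    raise ValueError(f"unknown step '{step}'")
                normalized.append(step)
            elif isinstance(step, dict) and len(step) == 1:
                name, params = next(iter(step.items()))
                normalized.append((name, dict(params)))
            else:
                name, params = step
                normalized.append((str(name), dict(params)))
        for step in normalized:
            if isinstance(step, tuple):
                name, params = step
                if name != "savgol":
                    raise ValueError(f"unknown step '{name}'")
                w, p = int(params["window"]), int(params["polyorder"])
                if w % 2 != 1 or p >= w:
                    raise ValueError("savgol window must be odd and > polyorder")
        object.__setattr__(self, "steps", tuple(normalized))

    def apply_row(self, x: np.ndarray, spacing: float = 1.0) -> np.ndarray:
        out = np.asarray(x, dtype=float)
        for step in self.steps:
            if step == "snv":
                out = snv(out)
            elif step == "mean_center":
                out = mean_center(out)
            else:
                _, params = step
                out = savgol(out, params["window"], params["polyorder"],
                             params.get("deriv", 0), spacing=spacing)
        return out

    def to_yaml(self) -> str:
        steps = [s if isinstance(s, str) else {s[0]: s[1]} for s in self.steps]
        return yaml.safe_dump({"steps": steps})

    @classmethod
    def from_yaml(cls, text: str) -> "PreprocessSpec":
        data = yaml.safe_load(text) or {}
        return cls(steps=tuple(data.get("steps", ())))


def apply_pipeline(ds: SpectralDataset, spec: PreprocessSpec) -> SpectralDataset:
    """Apply the pipeline row-wise; targets and metadata are unchanged."""
    spacing = ds.grid.channel_spacing_nm or 1.0
    rows = []
    for i in range(ds.n_samples):
        try:
            rows.append(spec.apply_row(ds.X[i], spacing=spacing))
        except ValueError as exc:
            raise ValueError(f"preprocessing failed at row {i}: {exc}") from exc
    return replace(ds, X=np.vstack(rows) if rows else ds.X.copy())


def augment_shift(spectrum: np.ndarray, shift_channels: float) -> np.ndarray:
    """Resample a spectrum at channel positions ``j - shift`` (linear interp).

    Positive shift moves features toward higher channel indices. Values
    outside the support are extended with the nearest edge value.
    """
    x = np.asarray(spectrum, dtype=float)
    q = x.shape[-1]
    if abs(shift_channels) >= q / 4:
        raise ValueError("shift too large (|shift| must be < Q/4)")
    pos = np.arange(q, dtype=float) - shift_channels
    if x.ndim == 1:
        return np.interp(pos, np.arange(q, dtype=float), x)
    return np.vstack([np.interp(pos, np.arange(q, dtype=float), row) for row in x])


def augment_baseline(spectrum: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Add a polynomial baseline in normalized channel position t in [0, 1].

    ``coeffs`` are ascending-power polynomial coefficients c0 + c1*t + ...
    """
    x = np.asarray(spectrum, dtype=float)
    c = np.asarray(coeffs, dtype=float)
    t = np.linspace(0.0, 1.0, x.shape[-1])
    return x + np.polynomial.polynomial.polyval(t, c)


def shift_one_band(ds: SpectralDataset) -> SpectralDataset:
    """Translate every spectrum by exactly one channel (evaluation perturbation).

    Channel ``j`` of the output equals channel ``j - 1`` of the input; the
    first channel is duplicated. The grid is unchanged.
    """
    if ds.n_channels < 2:
        raise ValueError("need at least 2 channels")
    X = np.empty_like(ds.X)
    X[:, 1:] = ds.X[:, :-1]
    X[:, 0] = ds.X[:, 0]
    return ds.with_X(X)


@dataclass(frozen=True)
class AugmentSpec:
    """Training-time augmentation: random sub-channel shift + random baseline.

    Randomness comes from a stream seeded by ``seed``, independent of
    weight-initialization randomness.
    """

    shift_channels_range: tuple = (-2.0, 2.0)
    baseline_poly_degree: int = 1
    baseline_coeff_sd: float = 0.0
    per_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.shift_channels_range
        if lo > hi:
            raise ValueError("shift range lo must be <= hi")
        if self.baseline_coeff_sd < 0:
            raise ValueError("baseline_coeff_sd must be >= 0")


def make_augmenter(spec: AugmentSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Build a stateful per-batch augmenter X -> X' (targets untouched)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.shift_channels_range

    def augment(X: np.ndarray) -> np.ndarray:
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            row = X[i]
            if hi > lo or lo != 0.0:
                row = augment_shift(row, rng.uniform(lo, hi))
            if spec.baseline_coeff_sd > 0:
                coeffs = rng.normal(0.0, spec.baseline_coeff_sd,
                                    size=spec.baseline_poly_degree + 1)
                row = augment_baseline(row, coeffs)
            out[i] = row
        return out

    return augment
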