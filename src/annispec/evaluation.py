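"""Metrics, evaluation protocols, and masking-based attribution maps.

Protocols mirror the three study designs: random train/test split,
instrument transfer (train on a parent instrument, test held-out samples
on every instrument), one-channel wavelength-shift perturbation, and
paired temperature series. Results are collected in tidy
:class:`ExperimentReport` tables (one row per model/condition/target).

Models enter the protocols through small adapter objects exposing
``name``, ``fit(ds)`` and ``predict(ds) -> (N, C)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annin_model import AnniNetConfig, AnniNetModel, TrainConfig
from .baselines import (fit_lssvr, fit_plsr, predict_lssvr, predict_plsr)
from .preprocessing import PreprocessSpec, shift_one_band
from .spectra_core import SpectralDataset

__all__ = [
    "rmse",
    "r2_score",
    "split_train_test",
    "concat_datasets",
    "ExperimentReport",
    "AttributionMap",
    "AnniNetAdapter",
    "PLSRAdapter",
    "LSSVRAdapter",
    "ConstantAdapter",
    "run_transfer_experiment",
    "run_shift_robustness",
    "shift_ratio",
    "run_temperature_experiment",
    "attribution_map",
]


# ------------------------------------------------------------------ metrics

def rmse(y_hat: np.ndarray, y: np.ndarray):
    """Root mean squared error over samples (per column for 2-D input)."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError("length mismatch")
    if y.shape[0] < 1:
        raise ValueError("need at least one sample")
    out = np.sqrt(np.mean((y_hat - y) ** 2, axis=0))
    return float(out) if out.ndim == 0 else out


def r2_score(y_hat: np.ndarray, y: np.ndarray):
    """Coefficient of determination, 1 - SSE/SST, SST about the test mean."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError("length mismatch")
    if y.shape[0] < 2:
        raise ValueError("need at least two samples")
    sst = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    if np.any(sst <= 0):
        raise ValueError("zero variance in reference values")
    sse = np.sum((y_hat - y) ** 2, axis=0)
    out = 1.0 - sse / sst
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------------------------ splits

def split_train_test(ds: SpectralDataset, train_fraction: float, seed: int):
    """Disjoint, exhaustive random split; size round(fraction * N) vs rest."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = ds.n_samples
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("degenerate split sizes")
    perm = np.random.default_rng(seed).permutation(n)
    return ds.subset(np.sort(perm[:n_train])), ds.subset(np.sort(perm[n_train:]))


def concat_datasets(datasets: Sequence[SpectralDataset],
                    id_prefixes: Optional[Sequence[str]] = None) -> SpectralDataset:
    """Stack paired-structure datasets row-wise (same grid and targets)."""
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.grid != first.grid or ds.target_names != first.target_names:
            raise ValueError("incompatible grids or target structure")
    if id_prefixes is None:
        id_prefixes = [f"d{i}_" for i in range(len(datasets))]
    aux_keys = set(first.aux)
    for ds in datasets[1:]:
        aux_keys &= set(ds.aux)
    return SpectralDataset(
        X=np.vstack([ds.X for ds in datasets]),
        grid=first.grid,
        Y=None if first.Y is None else np.vstack([ds.Y for ds in datasets]),
        target_names=first.target_names,
        target_units=first.target_units,
        sample_ids=tuple(p + s for p, ds in zip(id_prefixes, datasets)
                         for s in ds.sample_ids),
        aux={k: np.concatenate([ds.aux[k] for ds in datasets]) for k in aux_keys},
    )


# ------------------------------------------------------------------ adapters

class AnniNetAdapter:
    """Fits a fresh network per call; adapters are reusable across fits."""

    def __init__(self, config: Optional[AnniNetConfig] = None,
                 train_config: Optional[TrainConfig] = None, name: str = "annin"):
        self.name = name
        self.config = config or AnniNetConfig()
        self.train_config = train_config or TrainConfig()
        self.model: Optional[AnniNetModel] = None

    def fit(self, ds: SpectralDataset) -> "AnniNetAdapter":
        self.model = AnniNetModel(self.config, ds.n_channels, ds.n_targets,
                                  target_names=ds.target_names,
                                  init_seed=self.train_config.seed)
        self.model.fit(ds, self.train_config)
        return self

    def predict(self, ds: SpectralDataset) -> np.ndarray:
        return self.model.predict_dataset(ds)

    def without_prior(self) -> "AnniNetAdapter":
        cfg = replace(self.config, prior_dim=0)
        return AnniNetAdapter(cfg, self.train_config, name=self.name + "_noprior")


class PLSRAdapter:
    def __init__(self, n_components: int = 7,
                 preprocess: Optional[PreprocessSpec] = None, name: str = "plsr"):
        self.name = name
        self.n_components = n_components
        self.preprocess = preprocess
        self.model = None

    def fit(self, ds: SpectralDataset) -> "PLSRAdapter":
        n_comp = min(self.n_components, ds.n_samples - 1, ds.n_channels)
        self.model = fit_plsr(ds, n_comp, self.preprocess)
        return self

    def predict(self, ds: SpectralDataset) -> np.ndarray:
        return predict_plsr(self.model, ds)


class LSSVRAdapter:
    def __init__(self, gamma: float = 1e3, sigma: float = 10.0,
                 preprocess: Optional[PreprocessSpec] = None, name: str = "lssvr"):
        self.name = name
        self.gamma = gamma
        self.sigma = sigma
        self.preprocess = preprocess
        self.model = None

    def fit(self, ds: SpectralDataset) -> "LSSVRAdapter":
        self.model = fit_lssvr(ds, self.gamma, self.sigma, self.preprocess)
        return self

    def predict(self, ds: SpectralDataset) -> np.ndarray:
        return predict_lssvr(self.model, ds)


class ConstantAdapter:
    """Predicts the train-set target mean regardless of input (control model)."""

    def __init__(self, name: str = "constant"):
        self.name = name
        self.mean = None

    def fit(self, ds: SpectralDataset) -> "ConstantAdapter":
        self.mean = ds.Y.mean(axis=0)
        return self

    def predict(self, ds: SpectralDataset) -> np.ndarray:
        return np.tile(self.mean, (ds.n_samples, 1))


# ------------------------------------------------------------------ reports

@dataclass
class ExperimentReport:
    """Tidy results table plus run metadata."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.df) and (self.df["rmse"] < 0).any():
            raise ValueError("negative RMSE in report")
        if len(self.df) and "r2" in self.df and (self.df["r2"].dropna() > 1 + 1e-12).any():
            raise ValueError("R^2 above 1 in report")

    def to_csv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.df.to_csv(path, index=False)
        path.with_suffix(".meta.json").write_text(json.dumps(self.metadata, indent=2))

    @classmethod
    def from_csv(cls, path) -> "ExperimentReport":
        path = Path(path)
        meta_path = path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(df=pd.read_csv(path), metadata=meta)

    def render(self, index: Sequence[str] = ("model",),
               columns: Sequence[str] = ("target",)) -> str:
        """Text table of RMSE values in the layout of the study tables."""
        pivot = self.df.pivot_table(values="rmse", index=list(index),
                                    columns=list(columns), aggfunc="mean")
        return pivot.to_string(float_format=lambda v: f"{v:.4g}")


def _score_rows(model_name: str, pred: np.ndarray, ds: SpectralDataset,
                **cond) -> list:
    rows = []
    err = rmse(pred, ds.Y)
    r2 = r2_score(pred, ds.Y)
    err = np.atleast_1d(err)
    r2 = np.atleast_1d(r2)
    for j, target in enumerate(ds.target_names):
        rows.append({"model": model_name, **cond, "target": target,
                     "rmse": float(err[j]), "r2": float(r2[j])})
    return rows


# ------------------------------------------------------------------ protocols

def run_transfer_experiment(models: Sequence, datasets: dict, n_train: int,
                            seed: int = 0) -> ExperimentReport:
    """Instrument-transfer protocol on paired datasets.

    For each parent instrument, ``n_train`` randomly selected samples train
    each model; the held-out samples are scored on every instrument
    (the parent is included as one of the children). The sample selection
    is shared across models so the comparison is paired.
    """
    labels = list(datasets)
    first = datasets[labels[0]]
    n = first.n_samples
    for label in labels[1:]:
        if datasets[label].n_samples != n or datasets[label].sample_ids != first.sample_ids:
            raise ValueError("unpaired datasets (sample ids differ)")
    if n_train >= n:
        raise ValueError("n_train must be < N")
    rows = []
    for parent in labels:
        perm = np.random.default_rng([seed, _stable_hash(parent)]).permutation(n)
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        train_ds = datasets[parent].subset(train_idx)
        for model in models:
            model.fit(train_ds)
            for child in labels:
                test_ds = datasets[child].subset(test_idx)
                pred = model.predict(test_ds)
                rows.extend(_score_rows(model.name, pred, test_ds,
                                        parent=parent, child=child))
    return ExperimentReport(pd.DataFrame(rows), metadata={
        "experiment": "transfer", "n_train": n_train, "seed": seed,
        "instruments": labels})


def run_shift_robustness(models: Sequence, ds: SpectralDataset, seed: int = 0,
                         train_fraction: float = 0.75) -> ExperimentReport:
    """Score each model on the test set and on its one-channel-shifted copy."""
    train_ds, test_ds = split_train_test(ds, train_fraction, seed)
    shifted = shift_one_band(test_ds)
    rows = []
    for model in models:
        model.fit(train_ds)
        rows.extend(_score_rows(model.name, model.predict(test_ds), test_ds,
                                condition="unshifted"))
        rows.extend(_score_rows(model.name, model.predict(shifted), shifted,
                                condition="shifted"))
    return ExperimentReport(pd.DataFrame(rows), metadata={
        "experiment": "shift", "seed": seed, "train_fraction": train_fraction})


def shift_ratio(report: ExperimentReport) -> pd.DataFrame:
    """RMSE(shifted) / RMSE(unshifted) per model and target."""
    wide = report.df.pivot_table(values="rmse", index=["model", "target"],
                                 columns="condition")
    wide["ratio"] = wide["shifted"] / wide["unshifted"]
    return wide.reset_index()


def run_temperature_experiment(models: Sequence, ds_a: SpectralDataset,
                               ds_b: SpectralDataset, seed: int = 0,
                               train_fraction: float = 0.75,
                               labels: tuple = ("20C", "30C")) -> ExperimentReport:
    """Each series alone plus the pooled series (split stratified by series).

    Any model exposing ``without_prior()`` is additionally run on the
    pooled condition without its auxiliary input.
    """
    if ds_a.target_names != ds_b.target_names:
        raise ValueError("series have different target structure")
    la, lb = labels
    tr_a, te_a = split_train_test(ds_a, train_fraction, seed)
    tr_b, te_b = split_train_test(ds_b, train_fraction, seed + 1)
    conditions = {
        la: (tr_a, te_a),
        lb: (tr_b, te_b),
        f"{la}+{lb}": (concat_datasets([tr_a, tr_b], [f"{la}_", f"{lb}_"]),
                       concat_datasets([te_a, te_b], [f"{la}_", f"{lb}_"])),
    }
    rows = []
    pooled_label = f"{la}+{lb}"
    for model in models:
        for cond, (tr, te) in conditions.items():
            model.fit(tr)
            rows.extend(_score_rows(model.name, model.predict(te), te,
                                    condition=cond))
        if hasattr(model, "without_prior"):
            nop = model.without_prior()
            tr, te = conditions[pooled_label]
            nop.fit(tr)
            rows.extend(_score_rows(nop.name, nop.predict(te), te,
                                    condition=pooled_label))
    return ExperimentReport(pd.DataFrame(rows), metadata={
        "experiment": "temperature", "seed": seed,
        "train_fraction": train_fraction, "labels": list(labels)})


# ------------------------------------------------------------------ attribution

@dataclass
class AttributionMap:
    """Per-window, per-target prediction-error increase under masking."""

    window_starts: np.ndarray
    window_width: int
    values: np.ndarray  # (n_windows, C)
    target_names: tuple
    wavelengths_nm: Optional[np.ndarray] = None

    def peak_window(self, target: str) -> tuple:
        """(start_channel, end_channel) of the highest-attribution window."""
        j = self.target_names.index(target)
        i = int(np.argmax(self.values[:, j]))
        return int(self.window_starts[i]), int(self.window_starts[i]) + self.window_width

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.target_names))
        df.insert(0, "window_start", self.window_starts)
        df.insert(1, "window_width", self.window_width)
        return df


def _mask_window(X: np.ndarray, start: int, width: int, policy: str,
                 fill: Optional[np.ndarray] = None) -> np.ndarray:
    end = min(start + width, X.shape[1])
    out = X.copy()
    if policy == "identity":
        return out
    if policy == "zero":
        out[:, start:end] = 0.0
        return out
    if policy == "mean":
        out[:, start:end] = fill[start:end]
        return out
    if policy == "interp":
        left = X[:, start - 1] if start > 0 else X[:, end] if end < X.shape[1] else X[:, start]
        right = X[:, end] if end < X.shape[1] else left
        w = np.linspace(0.0, 1.0, end - start + 2)[1:-1]
        out[:, start:end] = left[:, None] * (1 - w) + right[:, None] * w
        return out
    raise ValueError(f"unknown mask policy '{policy}'")


def attribution_map(model, ds_test: SpectralDataset, window_width: Optional[int] = None,
                    stride: Optional[int] = None,
                    mask_value_policy: str = "interp") -> AttributionMap:
    """Slide a mask over the spectrum and measure the prediction-error increase.

    ``values[w, j]`` is RMSE(masked) - RMSE(unmasked) for window ``w`` and
    target ``j``; large values mark spectral regions the model relies on.
    The model is never modified.
    """
    q = ds_test.n_channels
    if window_width is None:
        window_width = -(-q // 32)
    if window_width < 1 or window_width > q:
        raise ValueError("window width must be in [1, Q]")
    if stride is None:
        stride = max(1, window_width // 2)
    starts = list(range(0, q - window_width + 1, stride))
    if starts[-1] != q - window_width:
        starts.append(q - window_width)
    base_rmse = np.atleast_1d(rmse(model.predict(ds_test), ds_test.Y))
    fill = ds_test.X.mean(axis=0)
    values = np.empty((len(starts), ds_test.n_targets))
    for i, start in enumerate(starts):
        masked = ds_test.with_X(_mask_window(ds_test.X, start, window_width,
                                             mask_value_policy, fill))
        masked_rmse = np.atleast_1d(rmse(model.predict(masked), masked.Y))
        values[i] = masked_rmse - base_rmse
    return AttributionMap(window_starts=np.array(starts), window_width=window_width,
                          values=values, target_names=ds_test.target_names,
                          wavelengths_nm=ds_test.grid.wavelengths_nm.copy())


def _stable_hash(label: str) -> int:
    import zlib
    return zlib.crc32(label.encode("utf-8"))
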