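"""Multi-task convolutional network for spectral regression.

The network couples three parts:

* an encoder (convolution + SELU + max-pooling blocks) mapping a spectrum
  of length Q to a feature map of shape (p, k) with p < Q;
* a decoder (up-sampling + convolution blocks) reconstructing the spectrum
  from the feature map, used only during training;
* a dense regression head (SELU hidden layers, softplus output) predicting
  the C target concentrations, optionally consuming an auxiliary scalar
  (e.g. sample temperature) concatenated at configured layers.

Training minimizes the sum of the mean per-sample reconstruction RMSE and
the mean per-sample regression RMSE, with dropout on the shared feature
map and optional wavelength-shift / baseline augmentation of each batch.

Spectra and targets are standardized internally: spectra by a global
train-set mean/sd, targets per column by an affine map that sends the
train minimum to ``TARGET_MARGIN`` and scales by the column sd, so the
strictly positive softplus output can cover the target range. Positivity
is therefore guaranteed on the internal scale; physical-scale predictions
are obtained by inverting the affine map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import _nn
from ._nn import SELU_ALPHA, SELU_LAMBDA
from .preprocessing import AugmentSpec, make_augmenter
from .spectra_core import SpectralDataset

__all__ = [
    "FeatureMap",
    "AnniNetConfig",
    "TrainConfig",
    "AnniNetModel",
    "selu",
    "softplus",
    "rmse_reconstruction",
    "rmse_regression",
    "train",
    "predict",
    "encode",
    "decode",
    "regress",
]

TARGET_MARGIN = 0.5  # internal offset keeping scaled targets inside softplus range


def selu(x, lam: float = SELU_LAMBDA, alpha: float = SELU_ALPHA):
    """Piecewise scaled exponential linear unit."""
    return _nn.selu(x, lam, alpha)


def softplus(x):
    """ln(1 + e^x), overflow-safe."""
    return _nn.softplus(x)


def rmse_reconstruction(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Per-sample reconstruction error sqrt(sum_j (x_hat_j - x_j)^2 / Q)."""
    x_hat = np.asarray(x_hat, dtype=float)
    x = np.asarray(x, dtype=float)
    if x_hat.shape != x.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((x_hat - x) ** 2)))


def rmse_regression(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Per-sample regression error sqrt(sum_j (y_hat_j - y_j)^2 / C)."""
    return rmse_reconstruction(y_hat, y)


@dataclass(frozen=True)
class FeatureMap:
    """Encoder output for one sample: p pooled positions x k filters."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] < 1:
            raise ValueError("feature map must be p x k with k >= 1")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnniNetConfig:
    """Architecture hyperparameters; defaults are the pinned reference setup."""

    k_filters: int = 16
    kernel_width: int = 9
    n_conv_blocks: int = 2
    pool_factor: int = 4
    dense_widths: tuple = (64, 32)
    dropout_rate: float = 0.2
    selu_lambda: float = SELU_LAMBDA
    selu_alpha: float = SELU_ALPHA
    prior_dim: int = 0
    prior_injection_layers: tuple = (0,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dense_widths", tuple(self.dense_widths))
        object.__setattr__(self, "prior_injection_layers",
                           tuple(self.prior_injection_layers))
        if self.k_filters < 1 or self.n_conv_blocks < 1:
            raise ValueError("k_filters and n_conv_blocks must be >= 1")
        if self.kernel_width % 2 != 1 or self.kernel_width < 1:
            raise ValueError("kernel_width must be odd and positive")
        if self.pool_factor < 2:
            raise ValueError("pool_factor must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.prior_dim < 0:
            raise ValueError("prior_dim must be >= 0")

    def pooled_length(self, q: int) -> int:
        """Feature-map length p after all pooling blocks (ceil division)."""
        p = q
        for _ in range(self.n_conv_blocks):
            p = -(-p // self.pool_factor)
        return p


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    augment: Optional[AugmentSpec] = None
    loss_weights: tuple = (1.0, 1.0)  # (w_recon, w_regr)
    early_stop_patience: Optional[int] = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        w_recon, w_regr = self.loss_weights
        if w_recon < 0 or w_regr <= 0:
            raise ValueError("loss weights must be nonnegative (regression > 0)")


class AnniNetModel:
    """Encoder/decoder/regression network with internal scalers."""

    def __init__(self, config: AnniNetConfig, n_channels: int, n_targets: int,
                 target_names=(), init_seed: int = 0):
        self.config = config
        self.n_channels = int(n_channels)
        self.n_targets = int(n_targets)
        self.target_names = tuple(target_names) or tuple(
            f"y{j}" for j in range(n_targets))
        self.fitted = False
        self.training_history: list = []
        self.p = config.pooled_length(self.n_channels)
        if self.p >= self.n_channels:
            raise ValueError("pooling must reduce the spectrum (p < Q)")
        # scalers (identity until fitted)
        self.x_mean, self.x_sd = 0.0, 1.0
        self.y_shift = np.zeros(self.n_targets)
        self.y_scale = np.ones(self.n_targets)
        self.prior_mean = np.zeros(max(config.prior_dim, 1))
        self.prior_sd = np.ones(max(config.prior_dim, 1))
        self._build(np.random.default_rng([init_seed, 0xA11]))

    # ------------------------------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        act = lambda: _nn.Selu(cfg.selu_lambda, cfg.selu_alpha)
        self.enc = []
        c_in = 1
        for _ in range(cfg.n_conv_blocks):
            self.enc.append(_nn.Conv1d(c_in, cfg.k_filters, cfg.kernel_width, rng))
            self.enc.append(act())
            self.enc.append(_nn.MaxPool1d(cfg.pool_factor))
            c_in = cfg.k_filters
        self.feature_dropout = _nn.Dropout(cfg.dropout_rate)
        self.dec = []
        for _ in range(cfg.n_conv_blocks):
            self.dec.append(_nn.Upsample1d(cfg.pool_factor))
            self.dec.append(_nn.Conv1d(cfg.k_filters, cfg.k_filters,
                                       cfg.kernel_width, rng))
            self.dec.append(act())
        self.dec.append(_nn.Conv1d(cfg.k_filters, 1, cfg.kernel_width, rng))
        self.dec.append(_nn.Crop1d(self.n_channels))
        # dense head: hidden layers (SELU) then output layer (softplus)
        self.head = []
        self.head_acts = []
        n_in = cfg.k_filters * self.p
        widths = list(cfg.dense_widths) + [self.n_targets]
        for i, width in enumerate(widths):
            if cfg.prior_dim > 0 and i in cfg.prior_injection_layers:
                n_in += cfg.prior_dim
            self.head.append(_nn.Dense(n_in, width, rng))
            self.head_acts.append(_nn.Softplus() if i == len(widths) - 1 else act())
            n_in = width

    def parameters(self):
        params = []
        for layer in self.enc + self.dec + self.head:
            params.extend(layer.parameters())
        return params

    def decoder_parameters(self):
        params = []
        for layer in self.dec:
            params.extend(layer.parameters())
        return params

    # ------------------------------------------------------------------
    # forward / backward on the internal (scaled) representation
    def _encode_forward(self, xs: np.ndarray, train: bool, rng=None) -> np.ndarray:
        h = xs[:, None, :]  # (N, 1, Q)
        for layer in self.enc:
            h = layer.forward(h)
        return self.feature_dropout.forward(h, train, rng)  # (N, k, p)

    def _encode_backward(self, g: np.ndarray) -> None:
        g = self.feature_dropout.backward(g)
        for layer in reversed(self.enc):
            g = layer.backward(g)

    def _decode_forward(self, m: np.ndarray) -> np.ndarray:
        h = m
        for layer in self.dec:
            h = layer.forward(h)
        return h[:, 0, :]  # (N, Q)

    def _decode_backward(self, g: np.ndarray) -> np.ndarray:
        h = g[:, None, :]
        for layer in reversed(self.dec):
            h = layer.backward(h)
        return h

    def _head_forward(self, m: np.ndarray, prior_s: Optional[np.ndarray]) -> np.ndarray:
        cfg = self.config
        h = m.reshape(m.shape[0], -1)
        self._head_injected = []
        for i, (dense, act) in enumerate(zip(self.head, self.head_acts)):
            injected = cfg.prior_dim > 0 and i in cfg.prior_injection_layers
            if injected:
                h = np.concatenate([h, prior_s], axis=1)
            self._head_injected.append(injected)
            h = act.forward(dense.forward(h))
        return h  # (N, C), strictly positive

    def _head_backward(self, g: np.ndarray, m_shape) -> np.ndarray:
        cfg = self.config
        for i in reversed(range(len(self.head))):
            g = self.head_acts[i].backward(g)
            g = self.head[i].backward(g)
            if self._head_injected[i]:
                g = g[:, :-cfg.prior_dim]
        return g.reshape(m_shape)

    # ------------------------------------------------------------------
    # scaling helpers
    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd

    def _scale_y(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, dtype=float) - self.y_shift) / self.y_scale + TARGET_MARGIN

    def _unscale_y(self, Ys: np.ndarray) -> np.ndarray:
        return (Ys - TARGET_MARGIN) * self.y_scale + self.y_shift

    def _scale_prior(self, prior: Optional[np.ndarray], n: int) -> Optional[np.ndarray]:
        if self.config.prior_dim == 0:
            if prior is not None:
                raise ValueError("model has prior_dim=0 but a prior was given")
            return None
        if prior is None:
            raise ValueError("model requires a prior input (prior_dim > 0)")
        prior = np.asarray(prior, dtype=float)
        if prior.ndim == 1:
            prior = prior[:, None]
        if prior.shape != (n, self.config.prior_dim):
            raise ValueError("prior shape mismatch")
        return (prior - self.prior_mean) / self.prior_sd

    # ------------------------------------------------------------------
    def fit(self, ds: SpectralDataset, cfg: TrainConfig) -> "AnniNetModel":
        """Train on a dataset; records per-epoch loss components."""
        if ds.Y is None:
            raise ValueError("training requires targets")
        if ds.n_channels != self.n_channels:
            raise ValueError("channel count does not match model")
        prior = None
        if self.config.prior_dim > 0:
            temps = ds.temperatures
            if temps is None:
                raise ValueError("prior_dim > 0 requires temperature_C aux data")
            prior = temps[:, None]
            self.prior_mean = prior.mean(axis=0)
            sd = prior.std(axis=0)
            self.prior_sd = np.where(sd > 0, sd, 1.0)
        X, Y = ds.X, ds.Y
        self.x_mean = float(X.mean())
        self.x_sd = float(X.std()) or 1.0
        self.y_shift = Y.min(axis=0)
        scale = Y.std(axis=0)
        self.y_scale = np.where(scale > 0, scale, 1.0)

        w_recon, w_regr = cfg.loss_weights
        use_decoder = w_recon > 0
        params = self.parameters() if use_decoder else [
            p for layer in self.enc + self.head for p in layer.parameters()]
        opt = _nn.Adam(params, lr=cfg.learning_rate)
        dropout_rng = np.random.default_rng([cfg.seed, 0xD0])
        shuffle_rng = np.random.default_rng([cfg.seed, 0x5F])
        augment = make_augmenter(cfg.augment) if cfg.augment is not None else None

        n = ds.n_samples
        q, c = self.n_channels, self.n_targets
        self.training_history = []
        best = np.inf
        stale = 0
        for epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(n)
            recon_sum = 0.0
            regr_sum = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Xb = X[idx]
                if augment is not None:
                    Xb = augment(Xb)
                xs = self._scale_x(Xb)
                ys = self._scale_y(Y[idx])
                ps = self._scale_prior(prior[idx] if prior is not None else None,
                                       len(idx))
                opt.zero_grad()
                m = self._encode_forward(xs, train=True, rng=dropout_rng)
                y_raw = self._head_forward(m, ps)
                e_y = y_raw - ys
                r_y = np.sqrt(np.mean(e_y ** 2, axis=1))
                regr_term = float(np.mean(r_y))
                safe_y = np.maximum(r_y, 1e-12)
                d_y = w_regr * e_y / (c * safe_y[:, None] * len(idx))
                g_m = self._head_backward(d_y, m.shape)
                if use_decoder:
                    xs_hat = self._decode_forward(m)
                    e_x = xs_hat - xs
                    r_x = np.sqrt(np.mean(e_x ** 2, axis=1))
                    recon_term = float(np.mean(r_x))
                    safe_x = np.maximum(r_x, 1e-12)
                    d_x = w_recon * e_x / (q * safe_x[:, None] * len(idx))
                    g_m = g_m + self._decode_backward(d_x)
                else:
                    recon_term = 0.0
                self._encode_backward(g_m)
                opt.step()
                recon_sum += recon_term * len(idx)
                regr_sum += regr_term * len(idx)
            recon_epoch = recon_sum / n
            regr_epoch = regr_sum / n
            total = w_recon * recon_epoch + w_regr * regr_epoch
            if not np.isfinite(total):
                raise RuntimeError(f"NaN loss at epoch {epoch}")
            self.training_history.append({
                "epoch": epoch, "loss": total,
                "recon_rmse": recon_epoch, "regr_rmse": regr_epoch,
            })
            if cfg.early_stop_patience is not None:
                if total < best - 1e-9:
                    best, stale = total, 0
                else:
                    stale += 1
                    if stale > cfg.early_stop_patience:
                        break
        self.fitted = True
        return self

    # ------------------------------------------------------------------
    def encode(self, X: np.ndarray) -> np.ndarray:
        """Feature maps (N, p, k) for raw spectra; dropout inactive."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_channels:
            raise ValueError("channel count does not match model")
        m = self._encode_forward(self._scale_x(X), train=False)
        return m.transpose(0, 2, 1)  # (N, p, k)

    def decode(self, maps: np.ndarray) -> np.ndarray:
        """Reconstruct spectra (N, Q) in original absorbance units."""
        maps = np.asarray(maps, dtype=float)
        if maps.ndim == 2:
            maps = maps[None]
        if maps.shape[1:] != (self.p, self.config.k_filters):
            raise ValueError("feature map shape does not match model")
        xs_hat = self._decode_forward(maps.transpose(0, 2, 1))
        return xs_hat * self.x_sd + self.x_mean

    def regress(self, maps: np.ndarray, prior: Optional[np.ndarray] = None) -> np.ndarray:
        """Raw head outputs (N, C): strictly positive softplus activations."""
        maps = np.asarray(maps, dtype=float)
        if maps.ndim == 2:
            maps = maps[None]
        if maps.shape[1:] != (self.p, self.config.k_filters):
            raise ValueError("feature map shape does not match model")
        ps = self._scale_prior(prior, maps.shape[0])
        return self._head_forward(maps.transpose(0, 2, 1), ps)

    def predict(self, X: np.ndarray, prior: Optional[np.ndarray] = None) -> np.ndarray:
        """Physical-scale predictions (N, C) for raw spectra; deterministic."""
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        return self._unscale_y(self.regress(self.encode(X), prior))

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Autoencoder round trip in original absorbance units."""
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        return self.decode(self.encode(np.atleast_2d(X)))

    def predict_dataset(self, ds: SpectralDataset) -> np.ndarray:
        prior = ds.temperatures if self.config.prior_dim > 0 else None
        return self.predict(ds.X, prior)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "config.yaml").write_text(yaml.safe_dump({
            "architecture": asdict(self.config),
            "n_channels": self.n_channels,
            "n_targets": self.n_targets,
            "target_names": list(self.target_names),
        }))
        arrays = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"p{i}"] = p.value
        np.savez(path / "params.npz", **arrays)
        (path / "scalers.json").write_text(json.dumps({
            "x_mean": self.x_mean, "x_sd": self.x_sd,
            "y_shift": self.y_shift.tolist(), "y_scale": self.y_scale.tolist(),
            "prior_mean": self.prior_mean.tolist(),
            "prior_sd": self.prior_sd.tolist(),
            "fitted": self.fitted,
        }))
        pd.DataFrame(self.training_history).to_csv(path / "history.csv", index=False)

    @classmethod
    def load(cls, path) -> "AnniNetModel":
        path = Path(path)
        meta = yaml.safe_load((path / "config.yaml").read_text())
        arch = dict(meta["architecture"])
        arch["dense_widths"] = tuple(arch["dense_widths"])
        arch["prior_injection_layers"] = tuple(arch["prior_injection_layers"])
        model = cls(AnniNetConfig(**arch), meta["n_channels"], meta["n_targets"],
                    target_names=meta["target_names"])
        with np.load(path / "params.npz") as data:
            for i, p in enumerate(model.parameters()):
                p.value[...] = data[f"p{i}"]
        sc = json.loads((path / "scalers.json").read_text())
        model.x_mean, model.x_sd = sc["x_mean"], sc["x_sd"]
        model.y_shift = np.array(sc["y_shift"])
        model.y_scale = np.array(sc["y_scale"])
        model.prior_mean = np.array(sc["prior_mean"])
        model.prior_sd = np.array(sc["prior_sd"])
        model.fitted = sc["fitted"]
        hist = path / "history.csv"
        if hist.exists():
            df = pd.read_csv(hist)
            model.training_history = df.to_dict("records") if len(df) else []
        return model


# functional wrappers ------------------------------------------------------

def train(model: AnniNetModel, ds: SpectralDataset, cfg: TrainConfig) -> AnniNetModel:
    return model.fit(ds, cfg)


def predict(model: AnniNetModel, X: np.ndarray, prior=None) -> np.ndarray:
    return model.predict(X, prior)


def encode(model: AnniNetModel, X: np.ndarray) -> np.ndarray:
    return model.encode(X)


def decode(model: AnniNetModel, maps: np.ndarray) -> np.ndarray:
    return model.decode(maps)


def regress(model: AnniNetModel, maps: np.ndarray, prior=None) -> np.ndarray:
    return model.regress(maps, prior)
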