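"""Classical comparison methods: PLSR and RBF-kernel least-squares SVR.

PLSR is a thin wrapper over scikit-learn's NIPALS ``PLSRegression``
(multi-target PLS2, mean-centered). The LSSVR solves, per target column,
the least-squares SVM dual system

    [[0, 1^T], [1, K + I/gamma]] @ [b; alpha] = [0; y]

with RBF kernel K(x, z) = exp(-||x - z||^2 / (2 sigma^2)); prediction is
sum_i alpha_i K(x, x_i) + b. Hyperparameters are chosen by K-fold
cross-validated grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .preprocessing import PreprocessSpec, apply_pipeline
from .spectra_core import SpectralDataset

__all__ = [
    "PLSRModel",
    "LSSVRModel",
    "fit_plsr",
    "predict_plsr",
    "select_components",
    "rbf_kernel",
    "fit_lssvr",
    "predict_lssvr",
    "tune_lssvr",
]


def _preprocess_X(ds: SpectralDataset, spec: Optional[PreprocessSpec]) -> np.ndarray:
    if spec is None or not spec.steps:
        return ds.X
    return apply_pipeline(ds, spec).X


@dataclass
class PLSRModel:
    n_components: int
    preprocess: Optional[PreprocessSpec]
    n_channels: int
    target_names: tuple
    _pls: PLSRegression = field(repr=False, default=None)

    @property
    def coefficients(self) -> np.ndarray:
        return self._pls.coef_


def fit_plsr(ds: SpectralDataset, n_components: int,
             preprocess: Optional[PreprocessSpec] = None) -> PLSRModel:
    """Fit a mean-centered multi-target PLS model on preprocessed spectra."""
    if ds.Y is None:
        raise ValueError("targets required")
    n, q = ds.X.shape
    bound = min(n - 1, q)
    if not 1 <= n_components <= bound:
        raise ValueError(f"n_components must be in [1, {bound}] for N={n}, Q={q}")
    Xp = _preprocess_X(ds, preprocess)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xp, ds.Y)
    return PLSRModel(n_components=n_components, preprocess=preprocess,
                     n_channels=q, target_names=ds.target_names, _pls=pls)


def predict_plsr(model: PLSRModel, ds: SpectralDataset) -> np.ndarray:
    if ds.n_channels != model.n_channels:
        raise ValueError("channel count does not match fitted model")
    Xp = _preprocess_X(ds, model.preprocess)
    return model._pls.predict(Xp)


def select_components(ds: SpectralDataset, candidates: Sequence[int],
                      folds: int = 5, seed: int = 0) -> int:
    """Component count minimizing mean CV RMSE; ties go to the smaller count."""
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("empty candidate range")
    if folds > ds.n_samples:
        raise ValueError("more folds than samples")
    if len(candidates) == 1:
        return candidates[0]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = {c: [] for c in candidates}
    for train_idx, test_idx in kf.split(ds.X):
        tr, te = ds.subset(train_idx), ds.subset(test_idx)
        for c in candidates:
            if c > min(len(train_idx) - 1, ds.n_channels):
                scores[c].append(np.inf)
                continue
            model = fit_plsr(tr, c)
            pred = predict_plsr(model, te)
            scores[c].append(float(np.sqrt(np.mean((pred - te.Y) ** 2))))
    means = {c: float(np.mean(v)) for c, v in scores.items()}
    best = min(means.values())
    return min(c for c, m in means.items() if m <= best + 1e-12)


def rbf_kernel(x: np.ndarray, z: np.ndarray, sigma: float) -> float:
    """exp(-||x - z||^2 / (2 sigma^2)) for two spectra."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("length mismatch")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return float(np.exp(-np.sum((x - z) ** 2) / (2.0 * sigma ** 2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(A, B, "sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma ** 2))


@dataclass
class LSSVRModel:
    alpha: np.ndarray  # (N, C) dual coefficients per target
    b: np.ndarray      # (C,) biases
    gamma: float
    sigma: float
    support_spectra: np.ndarray
    preprocess: Optional[PreprocessSpec]
    target_names: tuple


def fit_lssvr(ds: SpectralDataset, gamma: float, sigma: float,
              preprocess: Optional[PreprocessSpec] = None) -> LSSVRModel:
    """Solve the LS-SVM dual system exactly (one solve, all targets)."""
    if ds.Y is None:
        raise ValueError("targets required")
    if gamma <= 0 or sigma <= 0:
        raise ValueError("gamma and sigma must be > 0")
    Xp = _preprocess_X(ds, preprocess)
    n = Xp.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    K = _kernel_matrix(Xp, Xp, sigma)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.zeros((n + 1, ds.Y.shape[1]))
    rhs[1:] = ds.Y
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(A)
        raise np.linalg.LinAlgError(
            f"singular LS-SVM system (condition estimate {cond:.2e})") from exc
    return LSSVRModel(alpha=sol[1:], b=sol[0], gamma=gamma, sigma=sigma,
                      support_spectra=Xp.copy(), preprocess=preprocess,
                      target_names=ds.target_names)


def predict_lssvr(model: LSSVRModel, ds: SpectralDataset) -> np.ndarray:
    if ds.n_channels != model.support_spectra.shape[1]:
        raise ValueError("channel count does not match fitted model")
    Xp = _preprocess_X(ds, model.preprocess)
    K = _kernel_matrix(Xp, model.support_spectra, model.sigma)
    return K @ model.alpha + model.b


def tune_lssvr(ds: SpectralDataset, gamma_grid: Sequence[float],
               sigma_grid: Sequence[float], folds: int = 5, seed: int = 0):
    """Grid-search (gamma, sigma) by CV RMSE; ties prefer larger sigma then
    smaller gamma (the smoother model)."""
    gamma_grid = sorted(set(float(g) for g in gamma_grid))
    sigma_grid = sorted(set(float(s) for s in sigma_grid))
    if not gamma_grid or not sigma_grid:
        raise ValueError("empty grid")
    if len(gamma_grid) == 1 and len(sigma_grid) == 1:
        return gamma_grid[0], sigma_grid[0]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(ds.X))
    best = None
    for sigma in sorted(sigma_grid, reverse=True):
        for gamma in gamma_grid:
            errs = []
            for train_idx, test_idx in splits:
                tr, te = ds.subset(train_idx), ds.subset(test_idx)
                model = fit_lssvr(tr, gamma, sigma)
                pred = predict_lssvr(model, te)
                errs.append(float(np.sqrt(np.mean((pred - te.Y) ** 2))))
            score = float(np.mean(errs))
            if best is None or score < best[0] - 1e-12:
                best = (score, gamma, sigma)
    return best[1], best[2]
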