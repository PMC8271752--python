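"""Domain types and file I/O for spectral datasets.

A spectral dataset couples an ``N x Q`` absorbance matrix on a wavelength
grid with an optional ``N x C`` target table (constituent concentrations)
and per-sample auxiliary scalars such as sample temperature.

File dialect
------------
Spectra CSV: first column ``sample_id``, remaining column headers are
wavelengths in nm (decimal), one row per sample.

Targets CSV: first column ``sample_id``, then one column per target;
columns named ``temperature_C`` or ``instrument_id`` are treated as
auxiliary data, not targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "TargetVector",
    "SpectralDataset",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "crop_to_range",
    "DatasetError",
]

#: target-table column names that carry auxiliary data, not concentrations
AUX_COLUMNS = ("temperature_C", "instrument_id")


class DatasetError(ValueError):
    """Raised for invalid spectral dataset content or files."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm.

    ``channel_spacing_nm`` is set only when the grid is uniform; model
    modules that require a uniform grid check it via :meth:`is_uniform`.
    """

    wavelengths_nm: np.ndarray
    channel_spacing_nm: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise DatasetError("wavelength grid needs at least 2 channels")
        if not np.all(np.isfinite(wl)):
            raise DatasetError("non-finite wavelength values")
        if np.any(wl <= 0):
            raise DatasetError("wavelengths must be positive")
        if np.any(np.diff(wl) <= 0):
            raise DatasetError("non-monotone grid")
        diffs = np.diff(wl)
        if self.channel_spacing_nm is None and np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-9):
            object.__setattr__(self, "channel_spacing_nm", float(diffs[0]))

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths_nm, other.wavelengths_nm)

    @property
    def is_uniform(self) -> bool:
        return self.channel_spacing_nm is not None

    @classmethod
    def uniform(cls, lo_nm: float, hi_nm: float, spacing_nm: float) -> "WavelengthGrid":
        n = int(round((hi_nm - lo_nm) / spacing_nm)) + 1
        return cls(lo_nm + spacing_nm * np.arange(n))


@dataclass(frozen=True)
class Spectrum:
    """Single absorbance spectrum on a grid, with optional metadata."""

    values: np.ndarray
    grid: WavelengthGrid
    temperature_C: Optional[float] = None
    instrument_id: Optional[str] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != len(self.grid):
            raise DatasetError("spectrum length does not match grid")
        if not np.all(np.isfinite(v)):
            raise DatasetError("non-finite absorbance values")


@dataclass(frozen=True)
class TargetVector:
    """Per-sample constituent concentrations with names and units."""

    values: np.ndarray
    names: tuple
    units: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "units", tuple(self.units))
        if len(self.names) != v.size or len(self.units) != v.size:
            raise DatasetError("target names/units/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise DatasetError("duplicate target names")


@dataclass
class SpectralDataset:
    """``N x Q`` spectra plus optional ``N x C`` targets and aux scalars."""

    X: np.ndarray
    grid: WavelengthGrid
    Y: Optional[np.ndarray] = None
    target_names: tuple = ()
    target_units: tuple = ()
    sample_ids: tuple = ()
    aux: dict = field(default_factory=dict)
    instrument_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DatasetError("X must be 2-D (samples x channels)")
        if self.Y is not None:
            self.Y = np.asarray(self.Y, dtype=float)
        self.target_names = tuple(self.target_names)
        self.target_units = tuple(self.target_units)
        if not self.sample_ids:
            self.sample_ids = tuple(f"s{i:04d}" for i in range(self.X.shape[0]))
        else:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.aux = {k: np.asarray(v, dtype=float) for k, v in self.aux.items()}
        violations = validate_dataset(self)
        if violations:
            raise DatasetError("; ".join(violations))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def n_targets(self) -> int:
        return 0 if self.Y is None else self.Y.shape[1]

    @property
    def temperatures(self) -> Optional[np.ndarray]:
        return self.aux.get("temperature_C")

    def subset(self, indices: Sequence[int]) -> "SpectralDataset":
        """Row subset (copy), preserving grid/metadata."""
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            X=self.X[idx].copy(),
            grid=self.grid,
            Y=None if self.Y is None else self.Y[idx].copy(),
            target_names=self.target_names,
            target_units=self.target_units,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            aux={k: v[idx].copy() for k, v in self.aux.items()},
            instrument_id=self.instrument_id,
        )

    def with_X(self, X: np.ndarray) -> "SpectralDataset":
        """Same dataset with the spectra matrix replaced."""
        return replace(self, X=np.asarray(X, dtype=float))


def validate_dataset(ds: SpectralDataset) -> list:
    """Report every type-invariant violation; empty list iff valid."""
    violations: list = []
    n, q = ds.X.shape
    if n == 0:
        violations.append("empty dataset (N=0)")
    if q != len(ds.grid):
        violations.append(f"X has {q} channels but grid has {len(ds.grid)}")
    bad = np.argwhere(~np.isfinite(ds.X))
    for r, c in bad[:20]:
        violations.append(f"non-finite value in X at row {r}, column {c}")
    if ds.Y is not None:
        if ds.Y.ndim != 2:
            violations.append("Y must be 2-D")
        else:
            if ds.Y.shape[0] != n:
                violations.append(f"Y has {ds.Y.shape[0]} rows, expected {n}")
            if len(ds.target_names) != ds.Y.shape[1]:
                violations.append("target_names length does not match Y columns")
            if ds.target_units and len(ds.target_units) != ds.Y.shape[1]:
                violations.append("target_units length does not match Y columns")
            badY = np.argwhere(~np.isfinite(ds.Y))
            for r, c in badY[:20]:
                violations.append(f"non-finite value in Y at row {r}, column {c}")
    if len(set(ds.target_names)) != len(ds.target_names):
        violations.append("duplicate target names")
    if len(ds.sample_ids) != n:
        violations.append(f"{len(ds.sample_ids)} sample ids for {n} rows")
    elif len(set(ds.sample_ids)) != n:
        violations.append("duplicate sample ids")
    for key, v in ds.aux.items():
        if v.shape[0] != n:
            violations.append(f"aux '{key}' has {v.shape[0]} rows, expected {n}")
        elif not np.all(np.isfinite(v)):
            violations.append(f"non-finite value in aux '{key}'")
    return violations


def read_dataset(spectra_path, targets_path=None) -> SpectralDataset:
    """Load a dataset from a spectra CSV and an optional targets CSV.

    Targets are joined to spectra by ``sample_id``; any id present in one
    file but not the other is an error.
    """
    spectra_path = Path(spectra_path)
    if not spectra_path.exists():
        raise DatasetError(f"missing file: {spectra_path}")
    df = pd.read_csv(spectra_path, dtype={"sample_id": str},
                     float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise DatasetError("spectra file must start with a 'sample_id' column")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise DatasetError(f"non-numeric wavelength header: {exc}") from exc
    if wavelengths.size >= 2 and np.any(np.diff(wavelengths) <= 0):
        raise DatasetError("non-monotone grid in spectra header")
    grid = WavelengthGrid(wavelengths)
    sample_ids = tuple(df["sample_id"])
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise DatasetError("spectra file contains missing or non-finite values")

    Y = None
    names: tuple = ()
    units: tuple = ()
    aux: dict = {}
    instrument = None
    if targets_path is not None:
        targets_path = Path(targets_path)
        if not targets_path.exists():
            raise DatasetError(f"missing file: {targets_path}")
        tdf = pd.read_csv(targets_path, dtype={"sample_id": str},
                          float_precision="round_trip")
        if tdf.columns[0] != "sample_id":
            raise DatasetError("targets file must start with a 'sample_id' column")
        orphans = sorted(set(sample_ids) ^ set(tdf["sample_id"]))
        if orphans:
            raise DatasetError(
                "sample-id mismatch between spectra and targets; orphan ids: "
                + ", ".join(orphans[:10])
            )
        tdf = tdf.set_index("sample_id").loc[list(sample_ids)]
        if "instrument_id" in tdf.columns:
            vals = tdf["instrument_id"].unique()
            instrument = str(vals[0]) if len(vals) == 1 else None
            tdf = tdf.drop(columns=["instrument_id"])
        for col in tdf.columns:
            if col in AUX_COLUMNS:
                aux[col] = tdf[col].to_numpy(dtype=float)
        target_cols = [c for c in tdf.columns if c not in AUX_COLUMNS]
        if target_cols:
            Y = tdf[target_cols].to_numpy(dtype=float)
            names = tuple(target_cols)
            units = tuple("" for _ in target_cols)
    return SpectralDataset(
        X=X, grid=grid, Y=Y, target_names=names, target_units=units,
        sample_ids=sample_ids, aux=aux, instrument_id=instrument,
    )


def write_dataset(ds: SpectralDataset, spectra_path, targets_path=None) -> None:
    """Write a dataset to CSV files readable by :func:`read_dataset`."""
    if ds.n_samples == 0:
        raise DatasetError("empty dataset")
    violations = validate_dataset(ds)
    if violations:
        raise DatasetError("; ".join(violations))
    sdf = pd.DataFrame(ds.X, columns=[repr(float(w)) for w in ds.grid.wavelengths_nm])
    sdf.insert(0, "sample_id", list(ds.sample_ids))
    Path(spectra_path).parent.mkdir(parents=True, exist_ok=True)
    sdf.to_csv(spectra_path, index=False, float_format="%.17g")
    if targets_path is None:
        return
    tdf = pd.DataFrame({"sample_id": list(ds.sample_ids)})
    if ds.Y is not None:
        for j, name in enumerate(ds.target_names):
            tdf[name] = ds.Y[:, j]
    for key, v in ds.aux.items():
        tdf[key] = v
    if ds.instrument_id is not None:
        tdf["instrument_id"] = ds.instrument_id
    tdf.to_csv(targets_path, index=False, float_format="%.17g")


def crop_to_range(ds: SpectralDataset, lo_nm: float, hi_nm: float) -> SpectralDataset:
    """Restrict the dataset to channels inside the closed interval [lo, hi]."""
    if lo_nm >= hi_nm:
        raise DatasetError("lo_nm must be < hi_nm")
    wl = ds.grid.wavelengths_nm
    mask = (wl >= lo_nm) & (wl <= hi_nm)
    if mask.sum() == 0:
        raise DatasetError("no channels in range")
    if mask.sum() < 2:
        raise DatasetError("fewer than 2 channels in range")
    return replace(ds, X=ds.X[:, mask].copy(), grid=WavelengthGrid(wl[mask]))
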