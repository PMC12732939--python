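"""Spectral dataset container and wide-CSV I/O.

The container every other module consumes: an absorbance matrix ``X``
(samples x channels), a strictly monotone wavelength axis, a reference
property vector ``y`` and unique sample identifiers.  Channel *indices*
(not axis values) are the canonical coordinate downstream, so both
increasing (nm) and decreasing (wavenumber) axes are accepted and
preserved as stored; unit tags are opaque strings and never converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpectralDataset", "WavelengthGrid", "make_wavelength_grid",
           "read_dataset", "write_dataset"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Inclusive arithmetic wavelength sequence ``start, start+step, ... <= stop``."""

    start: float
    stop: float
    step: float
    unit: str = "nm"

    @property
    def values(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.values)


def make_wavelength_grid(start: float, stop: float, step: float,
                         unit: str = "nm") -> WavelengthGrid:
    """Build an inclusive arithmetic grid; a partial last step is dropped.

    ``make_wavelength_grid(1100, 2500, 2)`` has 701 channels — the classic
    1100-2500 nm @ 2 nm diffuse-reflectance axis.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if stop < start:
        raise ValueError(f"stop ({stop}) must be >= start ({start})")
    return WavelengthGrid(float(start), float(stop), float(step), unit)


@dataclass
class SpectralDataset:
    """Absorbance matrix + wavelength axis + reference values + sample ids.

    Invariants (checked on construction): row counts of ``X``, ``y`` and
    ``sample_ids`` agree; column count of ``X`` matches ``wavelengths``;
    the axis is strictly monotone; no NaN anywhere.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    y: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    axis_unit: str = "nm"
    y_unit: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x channels)")
        n, p = self.X.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.y) != n or len(self.sample_ids) != n:
            raise ValueError(
                f"row mismatch: X has {n} samples, y has {len(self.y)}, "
                f"ids has {len(self.sample_ids)}")
        if len(self.wavelengths) != p:
            raise ValueError(
                f"X has {p} channels but axis has {len(self.wavelengths)}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        d = np.diff(self.wavelengths)
        if p > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength axis must be strictly monotone")
        if np.isnan(self.X).any():
            i, j = np.argwhere(np.isnan(self.X))[0]
            raise ValueError(
                f"NaN in X at sample {self.sample_ids[i]!r}, "
                f"channel {self.wavelengths[j]}")
        if np.isnan(self.y).any():
            i = int(np.flatnonzero(np.isnan(self.y))[0])
            raise ValueError(f"NaN in y at sample {self.sample_ids[i]!r}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "SpectralDataset":
        """Row subset (samples), keeping every channel."""
        idx = np.asarray(idx)
        return replace(self, X=self.X[idx], y=self.y[idx],
                       sample_ids=[self.sample_ids[i] for i in idx])

    def with_X(self, X: np.ndarray) -> "SpectralDataset":
        """Same metadata, replaced absorbance matrix (e.g. after preprocessing)."""
        return replace(self, X=np.asarray(X, dtype=float))

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and np.allclose(self.X, other.X, rtol=1e-12, atol=0)
                and np.allclose(self.wavelengths, other.wavelengths, rtol=1e-12)
                and np.allclose(self.y, other.y, rtol=1e-12, atol=0))


def read_dataset(path, response_column: str) -> SpectralDataset:
    """Read a wide CSV: first column sample id, one response column, the
    remaining (numeric-named) columns are wavelength channels in stored order.
    """
    df = pd.read_csv(path)
    if response_column not in df.columns:
        raise ValueError(f"response column {response_column!r} not in {path}")
    id_col = df.columns[0]
    chan_cols = [c for c in df.columns if c not in (id_col, response_column)]
    try:
        wavelengths = np.array([float(c) for c in chan_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column name: {exc}") from exc
    X = df[chan_cols].to_numpy(dtype=float)
    y = df[response_column].to_numpy(dtype=float)
    ids = df[id_col].astype(str).tolist()
    return SpectralDataset(X=X, wavelengths=wavelengths, y=y, sample_ids=ids,
                           y_unit=response_column)


def write_dataset(ds: SpectralDataset, path, response_column: str = "y"):
    """Write the wide-CSV dialect read by :func:`read_dataset`; round-trips
    to float precision."""
    if ds.n_samples == 0:
        raise ValueError("refusing to write an empty dataset")
    cols = {"sample_id": ds.sample_ids, response_column: ds.y}
    df = pd.DataFrame(cols)
    chan = pd.DataFrame(ds.X, columns=[repr(float(w)) for w in ds.wavelengths])
    df = pd.concat([df, chan], axis=1)
    df.to_csv(path, index=False, float_format="%.17g")
    return path
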