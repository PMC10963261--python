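"""Spectral power distributions on uniform wavelength grids.

A :class:`SpectralDistribution` holds a power density per nanometre —
irradiance (mW m⁻² nm⁻¹) or radiance (mW m⁻² sr⁻¹ nm⁻¹) — on a strictly
increasing, uniformly spaced wavelength grid.  All downstream colorimetry
assumes densities per nm, so file readers interpolate but never rescale
values measured on coarser grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectralDistribution", "resample_spectrum", "read_spectra_csv"]

_QUANTITIES = ("irradiance", "radiance")


class ResamplingError(ValueError):
    """Raised when a spectrum cannot be moved onto a requested grid."""


@dataclass(frozen=True)
class SpectralDistribution:
    """Power density per nm on a uniform, ascending wavelength grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    quantity: str = "irradiance"
    name: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or wl.size < 2 or vals.shape != wl.shape:
            raise ValueError("wavelengths and values must be matching 1-d arrays")
        steps = np.diff(wl)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValueError("wavelength grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("spectral values must be finite and non-negative")
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"quantity must be one of {_QUANTITIES}")

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def integral(self) -> float:
        """Trapezoidal integral over wavelength (total power)."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))

    def scaled(self, factor: float) -> "SpectralDistribution":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return SpectralDistribution(self.wavelengths_nm, self.values * factor,
                                    self.quantity, self.name)

    def __add__(self, other: "SpectralDistribution") -> "SpectralDistribution":
        if not np.array_equal(self.wavelengths_nm, other.wavelengths_nm):
            raise ValueError("spectra must share a wavelength grid to be added")
        if self.quantity != other.quantity:
            raise ValueError("cannot add irradiance to radiance")
        return SpectralDistribution(self.wavelengths_nm,
                                    self.values + other.values, self.quantity)


def resample_spectrum(spd: SpectralDistribution,
                      target_grid: np.ndarray) -> SpectralDistribution:
    """Move a spectrum onto ``target_grid`` (linear interpolation inside the
    measured range, zero extension outside).

    Raises :class:`ResamplingError` when the grids do not overlap.
    """
    target = np.asarray(target_grid, dtype=float)
    wl = spd.wavelengths_nm
    if target[0] > wl[-1] or target[-1] < wl[0]:
        raise ResamplingError(
            f"target grid {target[0]:g}-{target[-1]:g} nm does not overlap the "
            f"measured range {wl[0]:g}-{wl[-1]:g} nm")
    values = np.interp(target, wl, spd.values, left=0.0, right=0.0)
    return SpectralDistribution(target, values, spd.quantity, spd.name)


def read_spectra_csv(path, quantity: str = "irradiance") -> list[SpectralDistribution]:
    """Read a spectrum CSV: header ``wavelength_nm,<name>...``, one column per
    measured condition."""
    table = pd.read_csv(path)
    if table.columns[0] != "wavelength_nm":
        raise ValueError("first column must be 'wavelength_nm'")
    wl = table["wavelength_nm"].to_numpy(dtype=float)
    return [
        SpectralDistribution(wl, table[col].to_numpy(dtype=float), quantity, col)
        for col in table.columns[1:]
    ]
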