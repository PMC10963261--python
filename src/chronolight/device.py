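"""Multi-primary light-source model.

A device is a set of primary spectra measured at maximum drive, assumed
linear in drive weight, with a finite number of drive levels per primary
(e.g. 256 for 8-bit control).  The synthetic five-primary device used for
solver validation has Gaussian primaries peaking at 430, 480, 500, 550 and
630 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import AlphaOpicSummary, alpha_opic_quantities
from .observer import ObserverBasis, default_basis
from .spectra import SpectralDistribution

__all__ = ["DeviceModel", "gaussian_device", "predict_summary", "quantize_weights"]


@dataclass(frozen=True, eq=False)
class DeviceModel:
    """Linear multi-primary device: primaries at maximum drive + level count."""

    primaries: tuple              # SpectralDistribution, common grid
    levels: int = 256
    name: str = "device"

    def __post_init__(self):
        if len(self.primaries) < 2:
            raise ValueError("a device needs at least two primaries")
        if self.levels < 2:
            raise ValueError("a device needs at least two drive levels")
        grid = self.primaries[0].wavelengths_nm
        for p in self.primaries:
            if not np.array_equal(p.wavelengths_nm, grid):
                raise ValueError("all primaries must share one wavelength grid")

    @property
    def n_primaries(self) -> int:
        return len(self.primaries)

    @property
    def grid(self) -> np.ndarray:
        return self.primaries[0].wavelengths_nm

    def spectrum(self, weights) -> SpectralDistribution:
        """Output spectrum for a drive-weight vector in [0, 1]^P."""
        w = _check_weights(weights, self.n_primaries)
        values = sum(wi * p.values for wi, p in zip(w, self.primaries))
        return SpectralDistribution(self.grid, values,
                                    self.primaries[0].quantity, self.name)

    def alpha_opic_matrix(self, basis: ObserverBasis | None = None) -> np.ndarray:
        """(5, P) matrix: α-opic values of each primary at full drive, in
        canonical receptor order.  α-opic values of a mixture are M @ w."""
        return np.column_stack([
            alpha_opic_quantities(p, basis).as_vector() for p in self.primaries
        ])

    @classmethod
    def from_csv(cls, path, levels: int = 256, quantity: str = "irradiance",
                 name: str = "device") -> "DeviceModel":
        from .spectra import read_spectra_csv
        return cls(tuple(read_spectra_csv(path, quantity)), levels, name)

    def to_csv(self, path) -> None:
        table = pd.DataFrame({"wavelength_nm": self.grid})
        for i, p in enumerate(self.primaries):
            table[p.name or f"primary_{i}"] = p.values
        table.to_csv(path, index=False)


def _check_weights(weights, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {w.shape}")
    if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
        raise ValueError("weights must lie in [0, 1]")
    return np.clip(w, 0.0, 1.0)


def gaussian_device(peaks_nm=(430.0, 480.0, 500.0, 550.0, 630.0),
                    fwhm_nm: float = 20.0,
                    peak_density: float = 10.0,
                    levels: int = 256,
                    grid: np.ndarray | None = None) -> DeviceModel:
    """Synthetic device with Gaussian primaries.

    ``peak_density`` is the spectral irradiance at each primary's peak at
    full drive, in mW m⁻² nm⁻¹; the default gives a gamut comfortably
    containing a daylight-like background near 100 lux.
    """
    if grid is None:
        grid = default_basis().grid
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    primaries = []
    for peak in peaks_nm:
        values = peak_density * np.exp(-0.5 * ((grid - peak) / sigma) ** 2)
        primaries.append(SpectralDistribution(grid, values, "irradiance",
                                              f"primary_{peak:.0f}nm"))
    return DeviceModel(tuple(primaries), levels, "gaussian_device")


def predict_summary(device: DeviceModel, weights,
                    basis: ObserverBasis | None = None) -> AlphaOpicSummary:
    """α-opic summary of the device output at the given drive weights."""
    return alpha_opic_quantities(device.spectrum(weights), basis)


def quantize_weights(weights, levels: int) -> np.ndarray:
    """Round weights to the nearest device level (half rounds up)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    w = _check_weights(weights, len(np.asarray(weights)))
    steps = np.floor(w * (levels - 1) + 0.5)
    return steps / (levels - 1)


def weight_levels(weights, levels: int) -> np.ndarray:
    """Integer drive levels corresponding to (already quantized) weights."""
    w = np.asarray(weights, dtype=float)
    return np.rint(w * (levels - 1)).astype(int)
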