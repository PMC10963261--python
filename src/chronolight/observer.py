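"""The bundled standard observer.

The package carries a single 1-nm table (380–780 nm) with the CIE 1931 2°
colour-matching functions, the scotopic efficiency function V′(λ), the
relative spectral power distribution of illuminant D65, and peak-normalised
action spectra for the five retinal photoreceptor channels used in α-opic
colorimetry: L, M and S cones, rods and melanopsin.

The CMF, V′ and D65 columns are standard published tables.  The cone and
melanopic action spectra are model-generated approximations of the standard
α-opic sensitivities (visual-pigment template with pre-receptoral filtering;
see ``tools/build_observer_tables.py``), calibrated so that the α-opic
irradiance of D65 per photopic lux matches the published daylight efficacy
constant of each channel.  Every D65-referred quantity computed here —
equivalent daylight illuminance in particular — is therefore anchored to the
standard values, while local curve shape is approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .spectra import SpectralDistribution

__all__ = ["ObserverBasis", "RECEPTORS", "default_basis"]

#: Canonical receptor order used throughout the package.
RECEPTORS = ("lcone", "mcone", "scone", "rod", "mel")

MAX_LUMINOUS_EFFICACY = 683.002  # lm W⁻¹ at 555 nm


@dataclass(frozen=True, eq=False)
class ObserverBasis:
    """Action spectra and reference functions on a common 1-nm grid."""

    wavelengths_nm: np.ndarray
    action_spectra: dict          # receptor -> peak-normalised curve
    vlambda: np.ndarray           # photopic luminous efficiency (ybar)
    cmfs: np.ndarray              # (n, 3) xbar, ybar, zbar
    d65: SpectralDistribution     # relative spectral power distribution

    def __post_init__(self):
        for name in RECEPTORS:
            curve = self.action_spectra[name]
            if np.any(curve < 0) or not np.isclose(curve.max(), 1.0, rtol=1e-6):
                raise ValueError(f"action spectrum {name} must be >=0 with peak 1")

    @property
    def grid(self) -> np.ndarray:
        return self.wavelengths_nm

    def d65_at_illuminance(self, lux: float) -> SpectralDistribution:
        """D65 scaled to the requested photopic illuminance, in mW m⁻² nm⁻¹."""
        if lux < 0:
            raise ValueError("illuminance must be non-negative")
        photopic_per_unit = MAX_LUMINOUS_EFFICACY * np.trapezoid(
            self.d65.values * self.vlambda, self.wavelengths_nm) / 1000.0
        return self.d65.scaled(lux / photopic_per_unit)

    @lru_cache
    def daylight_efficacy(self) -> dict:
        """α-opic value of D65 per photopic lux (mW m⁻² lx⁻¹ per channel).

        Computed once from the bundled D65 spectrum; these constants define
        the equivalent-daylight normalisation.
        """
        ref = self.d65_at_illuminance(1.0)
        return {
            name: float(np.trapezoid(ref.values * self.action_spectra[name],
                                     self.wavelengths_nm))
            for name in RECEPTORS
        }


@lru_cache(maxsize=1)
def default_basis() -> ObserverBasis:
    """Load the packaged observer table."""
    with resources.files("chronolight.data").joinpath("observer_1nm.csv").open() as fh:
        table = pd.read_csv(fh)
    wl = table["wavelength_nm"].to_numpy(dtype=float)
    spectra = {name: table[col].to_numpy(dtype=float)
               for name, col in zip(RECEPTORS, ["lcone", "mcone", "scone",
                                                "rod", "mel"])}
    # guard against formatting loss: re-normalise peaks exactly to 1
    spectra = {k: v / v.max() for k, v in spectra.items()}
    return ObserverBasis(
        wavelengths_nm=wl,
        action_spectra=spectra,
        vlambda=table["ybar"].to_numpy(dtype=float),
        cmfs=table[["xbar", "ybar", "zbar"]].to_numpy(dtype=float),
        d65=SpectralDistribution(wl, table["d65"].to_numpy(dtype=float),
                                 "irradiance", "D65"),
    )
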