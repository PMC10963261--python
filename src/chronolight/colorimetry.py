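"""α-opic colorimetry: photoreceptor-weighted quantities of a light.

Given a spectral power distribution and the standard observer, this module
computes the five α-opic (ir)radiances, the photopic illuminance or
luminance, the CIE 1931 chromaticity, the equivalent-daylight values (EDI in
lux for irradiance input, EDL in cd m⁻² for radiance input) and per-receptor
Weber contrasts between a modulation and a background light.

Conventions
-----------
* Spectral input is a density in mW m⁻² nm⁻¹ (irradiance) or
  mW m⁻² sr⁻¹ nm⁻¹ (radiance); α-opic outputs keep the mW-based unit.
* The equivalent-daylight value of channel α is the photopic illuminance of
  D65 producing the same α-opic irradiance:  EDI_α = E_α / K_α, with K_α the
  α-opic irradiance of D65 at 1 lux, computed once from the bundled tables.
* Weber contrast is 100·(modulation − background)/background per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observer import MAX_LUMINOUS_EFFICACY, RECEPTORS, ObserverBasis, default_basis
from .spectra import SpectralDistribution, resample_spectrum

__all__ = [
    "AlphaOpicSummary", "ContrastVector", "alpha_opic_quantities",
    "equivalent_daylight_value", "weber_contrast",
]


@dataclass(frozen=True)
class AlphaOpicSummary:
    """α-opic and photometric description of one light."""

    alpha_opic: dict              # receptor -> mW m⁻² (or mW m⁻² sr⁻¹)
    edi: dict                     # receptor -> lux (or cd m⁻²)
    photopic: float               # lux (irradiance) or cd m⁻² (radiance)
    chromaticity: tuple | None    # (x, y), None when undefined (zero light)
    quantity: str = "irradiance"
    name: str = ""

    def __post_init__(self):
        if any(v < 0 for v in self.alpha_opic.values()) or self.photopic < 0:
            raise ValueError("α-opic and photopic values must be non-negative")
        if self.chromaticity is not None:
            x, y = self.chromaticity
            if not (0 <= x and 0 <= y and x + y <= 1 + 1e-12):
                raise ValueError("chromaticity outside the unit diagram")

    def as_vector(self) -> np.ndarray:
        """α-opic values in canonical receptor order."""
        return np.array([self.alpha_opic[r] for r in RECEPTORS])


@dataclass(frozen=True)
class ContrastVector:
    """Per-receptor Weber contrast, in percent."""

    contrast_pct: dict            # receptor -> %

    def as_vector(self) -> np.ndarray:
        return np.array([self.contrast_pct[r] for r in RECEPTORS])

    def __getitem__(self, receptor: str) -> float:
        return self.contrast_pct[receptor]


def alpha_opic_quantities(spd: SpectralDistribution,
                          basis: ObserverBasis | None = None) -> AlphaOpicSummary:
    """Compute the full α-opic summary of a spectrum.

    The spectrum is resampled to the observer grid if needed.  All integrals
    are trapezoidal on the common 1-nm grid.
    """
    basis = basis or default_basis()
    wl = basis.grid
    if not np.array_equal(spd.wavelengths_nm, wl):
        spd = resample_spectrum(spd, wl)
    vals = spd.values  # mW m⁻² nm⁻¹

    alpha = {r: float(np.trapezoid(vals * basis.action_spectra[r], wl))
             for r in RECEPTORS}
    # photopic: V(λ) integral, 683 lm/W, input in mW → /1000
    photopic = MAX_LUMINOUS_EFFICACY * float(
        np.trapezoid(vals * basis.vlambda, wl)) / 1000.0
    X, Y, Z = (float(np.trapezoid(vals * basis.cmfs[:, i], wl)) for i in range(3))
    total = X + Y + Z
    chromaticity = (X / total, Y / total) if total > 0 else None

    efficacy = basis.daylight_efficacy()
    edi = {r: alpha[r] / efficacy[r] for r in RECEPTORS}
    return AlphaOpicSummary(alpha, edi, photopic, chromaticity,
                            spd.quantity, spd.name)


def equivalent_daylight_value(alpha_value: float, receptor: str,
                              basis: ObserverBasis | None = None) -> float:
    """Equivalent daylight illuminance (lux) or luminance (cd m⁻²) for one
    α-opic value."""
    if receptor not in RECEPTORS:
        raise ValueError(f"unknown receptor {receptor!r}; expected one of {RECEPTORS}")
    if alpha_value < 0:
        raise ValueError("α-opic value must be non-negative")
    basis = basis or default_basis()
    return alpha_value / basis.daylight_efficacy()[receptor]


def weber_contrast(mod: AlphaOpicSummary, bg: AlphaOpicSummary) -> ContrastVector:
    """Per-receptor Weber contrast of a modulation against a background, %."""
    contrast = {}
    for r in RECEPTORS:
        denom = bg.alpha_opic[r]
        if denom <= 0:
            raise ZeroDivisionError(
                f"background α-opic value for channel {r!r} is zero")
        contrast[r] = 100.0 * (mod.alpha_opic[r] - denom) / denom
    return ContrastVector(contrast)
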