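"""Silent-substitution stimulus solver.

Finds drive weights for a multi-primary device producing

* a *background* whose five α-opic values match those of daylight (D65)
  scaled to a target illuminance, and
* *modulation* spectra achieving target Weber contrasts on selected
  photoreceptor channels — for the blue-dim / yellow-bright stimuli:
  ±S-cone contrast, ∓(L+M) contrast, with melanopsin silenced (0 %) and
  rods left unconstrained.

Because the device is linear in its drive weights, the α-opic values — and
therefore the Weber contrasts against a fixed background — are linear in the
weights.  Both problems are convex bounded linear least squares and are
solved globally and deterministically with :func:`scipy.optimize.lsq_linear`;
no random restarts are required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .colorimetry import ContrastVector, weber_contrast
from .device import DeviceModel, predict_summary, quantize_weights, weight_levels
from .observer import RECEPTORS, ObserverBasis, default_basis

__all__ = ["SubstitutionTarget", "SolverSolution", "solve_background",
           "solve_modulation", "GamutError"]

_OBJECTIVE_TOL = 1e-10


class GamutError(ValueError):
    """Requested output lies outside what the device can produce."""


@dataclass(frozen=True)
class SubstitutionTarget:
    """Target Weber contrasts (%) for the constrained receptor channels.

    ``constrained`` maps receptor names to target contrast; channels absent
    from the mapping (always the rods in this study) are left free.
    """

    constrained: dict
    label: str = ""

    def __post_init__(self):
        unknown = set(self.constrained) - set(RECEPTORS)
        if unknown:
            raise ValueError(f"unknown receptor channels: {sorted(unknown)}")

    @classmethod
    def silent_substitution(cls, s_contrast: float,
                            lm_contrast: float) -> "SubstitutionTarget":
        """Opponent S vs L+M target with melanopsin silenced.

        The L and M cones are individually constrained to the shared L+M
        value; melanopsin is fixed at exactly 0 %.
        """
        label = "blue-dim(+S-(L+M))" if s_contrast >= lm_contrast \
            else "yellow-bright(-S+(L+M))"
        return cls({"scone": float(s_contrast), "lcone": float(lm_contrast),
                    "mcone": float(lm_contrast), "mel": 0.0}, label)


@dataclass(frozen=True)
class SolverSolution:
    """Solved modulation: weights, achieved contrasts, diagnostics."""

    w_bg: np.ndarray
    w_mod: np.ndarray
    w_mod_quantized: np.ndarray
    drive_levels: np.ndarray
    contrast: ContrastVector            # pre-quantization
    contrast_quantized: ContrastVector  # at realised (quantized) weights
    objective: float                    # sum of squared contrast errors (%²)
    converged: bool
    target: SubstitutionTarget

    def report(self) -> dict:
        return {
            "target": dict(self.target.constrained),
            "label": self.target.label,
            "weights_background": self.w_bg.tolist(),
            "weights_modulation": self.w_mod.tolist(),
            "weights_modulation_quantized": self.w_mod_quantized.tolist(),
            "drive_levels": self.drive_levels.tolist(),
            "contrast_pct": dict(self.contrast.contrast_pct),
            "contrast_quantized_pct": dict(self.contrast_quantized.contrast_pct),
            "objective": self.objective,
            "converged": self.converged,
        }


def solve_background(device: DeviceModel, basis: ObserverBasis | None = None,
                     target_illuminance: float = 93.5):
    """Weights matching the device output to the α-opic profile of D65 at the
    requested photopic illuminance.

    Minimises the squared *relative* error of the five α-opic values, so
    every channel counts equally regardless of magnitude.  Returns
    ``(weights, residual)`` where residual is the root-sum-square relative
    α-opic error of the best feasible solution.
    """
    basis = basis or default_basis()
    if target_illuminance == 0:
        return np.zeros(device.n_primaries), 0.0
    target = predict_summary(device, np.ones(device.n_primaries), basis)
    max_lux = target.photopic
    if target_illuminance > max_lux:
        raise GamutError(
            f"target illuminance {target_illuminance:g} lux exceeds the "
            f"device maximum of {max_lux:.4g} lux")

    from .colorimetry import alpha_opic_quantities
    d65 = alpha_opic_quantities(basis.d65_at_illuminance(target_illuminance),
                                basis).as_vector()
    M = device.alpha_opic_matrix(basis)            # (5, P)
    A = M / d65[:, None]                           # relative-error design
    res = lsq_linear(A, np.ones(len(RECEPTORS)), bounds=(0.0, 1.0),
                     tol=1e-14)
    residual = float(np.sqrt(np.sum((A @ res.x - 1.0) ** 2)))
    return np.clip(res.x, 0.0, 1.0), residual


def solve_modulation(device: DeviceModel, w_bg,
                     target: SubstitutionTarget,
                     basis: ObserverBasis | None = None) -> SolverSolution:
    """Find modulation weights achieving the target contrasts.

    Minimises Σ (achieved − desired)² over the constrained channels subject
    to the weight box constraints.  The achieved contrast of channel r is
    100·(M_r·w − M_r·w_bg)/(M_r·w_bg), linear in w, so the global optimum is
    found by bounded linear least squares.  ``converged`` is set when the
    residual objective is numerically zero; with fewer primaries than
    constrained channels the best least-squares solution is returned with
    ``converged=False``.
    """
    basis = basis or default_basis()
    w_bg = np.asarray(w_bg, dtype=float)
    M = device.alpha_opic_matrix(basis)
    bg_alpha = M @ w_bg
    idx = [RECEPTORS.index(r) for r in target.constrained]
    if np.any(bg_alpha[idx] <= 0):
        raise ValueError("background α-opic values must be positive on all "
                         "constrained channels")
    desired = np.array([target.constrained[RECEPTORS[i]] for i in idx])
    # contrast(w) = 100 * (M w - M w_bg) / (M w_bg), rows restricted to idx
    A = 100.0 * M[idx] / bg_alpha[idx, None]
    b = desired + 100.0
    # tiny ridge toward the background weights: with more primaries than
    # constraints the exact solutions form an affine set, and the preferred
    # one is the minimal drive excursion (zero targets then return w_bg).
    eps = 1e-6 * np.linalg.norm(A)
    A_aug = np.vstack([A, eps * np.eye(device.n_primaries)])
    b_aug = np.concatenate([b, eps * w_bg])
    res = lsq_linear(A_aug, b_aug, bounds=(0.0, 1.0), tol=1e-14)
    w_mod = np.clip(res.x, 0.0, 1.0)
    objective = float(np.sum((A @ w_mod - b) ** 2))
    converged = bool(objective <= max(_OBJECTIVE_TOL,
                                      1e-12 * float(np.sum(b ** 2))))

    w_q = quantize_weights(w_mod, device.levels)
    bg_summary = predict_summary(device, w_bg, basis)
    contrast = weber_contrast(predict_summary(device, w_mod, basis), bg_summary)
    contrast_q = weber_contrast(predict_summary(device, w_q, basis), bg_summary)
    return SolverSolution(
        w_bg=w_bg, w_mod=w_mod, w_mod_quantized=w_q,
        drive_levels=weight_levels(w_q, device.levels),
        contrast=contrast, contrast_quantized=contrast_q,
        objective=objective, converged=converged, target=target)
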