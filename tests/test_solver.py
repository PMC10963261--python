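import numpy as np
import pytest

from chronolight import (alpha_opic_quantities, gaussian_device,
                         predict_summary, quantize_weights, solve_background,
                         solve_modulation, SubstitutionTarget, GamutError)
from chronolight.device import DeviceModel
from chronolight.spectra import SpectralDistribution


# -- predict_summary --------------------------------------------------------

def test_predict_zero_weights_zero_summary(device, basis):
    summary = predict_summary(device, np.zeros(5), basis)
    assert all(v == 0 for v in summary.alpha_opic.values())


def test_predict_single_primary(device, basis):
    w = np.zeros(5)
    w[2] = 1.0
    direct = alpha_opic_quantities(device.primaries[2], basis)
    via = predict_summary(device, w, basis)
    np.testing.assert_allclose(via.as_vector(), direct.as_vector(), rtol=1e-12)


def test_predict_linearity_two_primary_mean(basis):
    grid = basis.grid
    p1 = SpectralDistribution(grid, np.exp(-0.5 * ((grid - 450) / 10.0) ** 2))
    p2 = SpectralDistribution(grid, np.exp(-0.5 * ((grid - 600) / 10.0) ** 2))
    dev = DeviceModel((p1, p2))
    mean = predict_summary(dev, [0.5, 0.5], basis).as_vector()
    individual = (alpha_opic_quantities(p1, basis).as_vector()
                  + alpha_opic_quantities(p2, basis).as_vector()) / 2.0
    np.testing.assert_allclose(mean, individual, rtol=1e-12)


def test_predict_rejects_out_of_range_weights(device, basis):
    with pytest.raises(ValueError):
        predict_summary(device, [0.5, 1.2, 0.5, 0.5, 0.5], basis)


# -- background solving -----------------------------------------------------

def test_background_exact_recovery_on_masked_d65_device(basis):
    """Primaries that sum to D65 admit an exact background: residual ~ 0."""
    d65 = basis.d65_at_illuminance(93.5)
    mask = basis.grid < 550.0
    p1 = SpectralDistribution(basis.grid, np.where(mask, d65.values * 2, 0.0))
    p2 = SpectralDistribution(basis.grid, np.where(mask, 0.0, d65.values * 2))
    dev = DeviceModel((p1, p2))
    w, residual = solve_background(dev, basis, 93.5)
    assert residual < 1e-8
    np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-6)


def test_background_zero_illuminance(device, basis):
    w, residual = solve_background(device, basis, 0.0)
    assert np.all(w == 0) and residual == 0


def test_background_infeasible_reports_max(device, basis):
    with pytest.raises(GamutError, match="lux"):
        solve_background(device, basis, 1e6)


def test_background_d65_like_on_gaussian_device(device, basis, background):
    w, residual = background
    summary = predict_summary(device, w, basis)
    target = alpha_opic_quantities(basis.d65_at_illuminance(93.5), basis)
    np.testing.assert_allclose(summary.as_vector(), target.as_vector(),
                               rtol=0.05)


# -- modulation solving -----------------------------------------------------

def test_modulation_silences_melanopsin(device, basis, background):
    w_bg, _ = background
    for s, lm in ((25.0, -25.0), (-25.0, 25.0)):
        sol = solve_modulation(
            device, w_bg, SubstitutionTarget.silent_substitution(s, lm), basis)
        assert abs(sol.contrast["mel"]) < 0.5
        assert abs(sol.contrast_quantized["mel"]) <= 3.2
        assert sol.contrast["scone"] == pytest.approx(s, abs=0.01)
        assert sol.contrast["lcone"] == pytest.approx(lm, abs=0.01)
        assert sol.converged


def test_modulation_zero_target_returns_background(device, basis, background):
    w_bg, _ = background
    target = SubstitutionTarget({"scone": 0.0, "lcone": 0.0, "mcone": 0.0,
                                 "mel": 0.0})
    sol = solve_modulation(device, w_bg, target, basis)
    np.testing.assert_allclose(sol.w_mod, w_bg, atol=1e-9)
    assert sol.objective == pytest.approx(0.0, abs=1e-12)


def test_two_primary_toy_matches_closed_form(basis):
    """Two constraints, two primaries: the bounded LSQ must hit the exact
    2×2 linear solution when it is interior."""
    grid = basis.grid
    p1 = SpectralDistribution(grid, 5 * np.exp(-0.5 * ((grid - 460) / 12.0) ** 2))
    p2 = SpectralDistribution(grid, 5 * np.exp(-0.5 * ((grid - 580) / 12.0) ** 2))
    dev = DeviceModel((p1, p2))
    w_bg = np.array([0.5, 0.5])
    from chronolight.observer import RECEPTORS
    M = dev.alpha_opic_matrix(basis)
    idx = [RECEPTORS.index("scone"), RECEPTORS.index("mel")]
    A = 100.0 * M[idx] / (M[idx] @ w_bg)[:, None]
    # targets chosen so the unique 2×2 solution is the interior point below
    w_exact = np.array([0.62, 0.41])
    b = A @ w_exact
    target = SubstitutionTarget({"scone": b[0] - 100.0, "mel": b[1] - 100.0})
    sol = solve_modulation(dev, w_bg, target, basis)
    np.testing.assert_allclose(sol.w_mod, w_exact, atol=1e-8)
    assert sol.objective < 1e-14


def test_underdetermined_device_flags_not_converged(basis):
    grid = basis.grid
    p1 = SpectralDistribution(grid, np.exp(-0.5 * ((grid - 480) / 15.0) ** 2))
    p2 = SpectralDistribution(grid, np.exp(-0.5 * ((grid - 560) / 15.0) ** 2))
    dev = DeviceModel((p1, p2))
    sol = solve_modulation(dev, np.array([0.5, 0.5]),
                           SubstitutionTarget.silent_substitution(25.0, -25.0),
                           basis)
    assert not sol.converged
    assert sol.objective > 0


def test_pole_symmetry_of_excursions(device, basis, background):
    """Interior solutions: +c and −c poles give excursions of equal norm."""
    w_bg, _ = background
    sol_p = solve_modulation(device, w_bg,
                             SubstitutionTarget.silent_substitution(25, -25),
                             basis)
    sol_m = solve_modulation(device, w_bg,
                             SubstitutionTarget.silent_substitution(-25, 25),
                             basis)
    n_p = np.linalg.norm(sol_p.w_mod - w_bg)
    n_m = np.linalg.norm(sol_m.w_mod - w_bg)
    assert abs(n_p - n_m) / n_p < 0.01


def test_objective_never_increases_with_added_primary(basis):
    grid = basis.grid

    def gauss(peak):
        return SpectralDistribution(
            grid, 8 * np.exp(-0.5 * ((grid - peak) / 10.0) ** 2))

    small = DeviceModel((gauss(450), gauss(550)))
    big = DeviceModel((gauss(450), gauss(550), gauss(610)))
    target = SubstitutionTarget.silent_substitution(25.0, -25.0)
    w_bg_small = np.array([0.4, 0.4])
    w_bg_big = np.array([0.4, 0.4, 0.0])  # same background spectrum
    obj_small = solve_modulation(small, w_bg_small, target, basis).objective
    obj_big = solve_modulation(big, w_bg_big, target, basis).objective
    assert obj_big <= obj_small + 1e-9


def test_solver_matches_dense_grid_search_two_primaries(basis):
    """Global optimality check against exhaustive 1/512-step enumeration."""
    grid = basis.grid
    p1 = SpectralDistribution(grid, 6 * np.exp(-0.5 * ((grid - 470) / 14.0) ** 2))
    p2 = SpectralDistribution(grid, 6 * np.exp(-0.5 * ((grid - 590) / 14.0) ** 2))
    dev = DeviceModel((p1, p2))
    w_bg = np.array([0.45, 0.55])
    target = SubstitutionTarget.silent_substitution(20.0, -20.0)
    sol = solve_modulation(dev, w_bg, target, basis)

    from chronolight.observer import RECEPTORS
    M = dev.alpha_opic_matrix(basis)
    idx = [RECEPTORS.index(r) for r in target.constrained]
    A = 100.0 * M[idx] / (M[idx] @ w_bg)[:, None]
    b = np.array([target.constrained[RECEPTORS[i]] for i in idx]) + 100.0
    steps = np.arange(513) / 512.0
    W = np.stack(np.meshgrid(steps, steps), axis=-1).reshape(-1, 2)
    grid_obj = np.sum((W @ A.T - b) ** 2, axis=1).min()
    assert sol.objective <= grid_obj + 1e-9


# -- quantization -----------------------------------------------------------

def test_quantize_half_rounds_up():
    q = quantize_weights(np.array([0.5]), 256)
    assert q[0] == pytest.approx(128 / 255)


def test_quantize_on_grid_unchanged():
    w = np.array([0.0, 64 / 255, 1.0])
    np.testing.assert_array_equal(quantize_weights(w, 256), w)


def test_quantize_rejects_bad_levels():
    with pytest.raises(ValueError):
        quantize_weights(np.array([0.5]), 1)


def test_quantization_error_bounded_by_neighbour_enumeration(device, basis,
                                                             background, rng):
    """The realised contrast after quantization is at least as good as the
    worst ±1-level neighbour (sanity bound on the rounding perturbation)."""
    w_bg, _ = background
    target = SubstitutionTarget.silent_substitution(25.0, -25.0)
    sol = solve_modulation(device, w_bg, target, basis)
    from chronolight.observer import RECEPTORS
    M = device.alpha_opic_matrix(basis)
    bg_alpha = M @ w_bg
    step = 1.0 / (device.levels - 1)
    # worst per-channel contrast change over all ±1-level single moves
    worst = np.max(np.abs(100.0 * M * step / bg_alpha[:, None]))
    realised_shift = np.abs(sol.contrast_quantized.as_vector()
                            - sol.contrast.as_vector())
    assert np.all(realised_shift <= worst * device.n_primaries)
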