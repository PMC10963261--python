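import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chronolight.bayes import (LinearModelBF, interpret_bf, jzs_bf10_vectorized,
                               jzs_ttest_bf, lm_bf, rank_transform,
                               sequential_design_sim, _jzs_log_integrand)


def brute_force_jzs(t, n, r=np.sqrt(2) / 2, points=400_001):
    """Independent dense-grid integration of the JZS mixture on log g."""
    lg = np.linspace(-25.0, 25.0, points)
    vals = np.exp(_jzs_log_integrand(np.exp(lg), t, n, r) + lg)
    return np.trapezoid(vals, lg)


# -- JZS t-test BF ----------------------------------------------------------

def test_null_concordant_data_favour_h0():
    assert jzs_ttest_bf(t=0.0, n=12).bf10 < 1


def test_bf_from_raw_differences_matches_t_path(rng):
    x = rng.normal(0.5, 1.0, size=14)
    t = x.mean() / (x.std(ddof=1) / np.sqrt(x.size))
    assert jzs_ttest_bf(data=x).bf10 == pytest.approx(
        jzs_ttest_bf(t=t, n=x.size).bf10, rel=1e-10)


def test_quadrature_matches_brute_force_oracle(rng):
    for _ in range(20):
        t = rng.uniform(-4, 4)
        n = int(rng.integers(3, 40))
        mine = jzs_ttest_bf(t=t, n=n).bf10
        assert mine == pytest.approx(brute_force_jzs(t, n), rel=1e-6)


def test_quadrature_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    for t, n in ((1.5, 10), (3.2, 16), (0.0, 8), (-2.1, 12)):
        ref = float(pingouin.bayesfactor_ttest(t, n, paired=True))
        assert jzs_ttest_bf(t=t, n=n).bf10 == pytest.approx(ref, rel=1e-3)


def test_vectorized_path_agrees_with_adaptive():
    ts = np.linspace(-5, 5, 21)
    vec = jzs_bf10_vectorized(ts, 16)
    for t, v in zip(ts, vec):
        assert v == pytest.approx(jzs_ttest_bf(t=float(t), n=16).bf10,
                                  rel=1e-7)


def test_bf_monotone_in_absolute_t():
    ts = np.linspace(0.0, 6.0, 40)
    bfs = jzs_bf10_vectorized(ts, 16)
    assert np.all(np.diff(bfs) > 0)


def test_large_effect_at_n16_near_boundary():
    """d̂ = 0.8 at n = 16 (t = 3.2) sits just under the stopping boundary;
    the value is pinned by the independent brute-force oracle."""
    bf = jzs_ttest_bf(t=3.2, n=16).bf10
    assert bf == pytest.approx(brute_force_jzs(3.2, 16), rel=1e-8)
    assert 8.0 < bf < 10.0
    assert jzs_ttest_bf(t=3.6, n=16).bf10 > 10


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        jzs_ttest_bf(t=np.nan, n=10)
    with pytest.raises(ValueError):
        jzs_ttest_bf(t=1.0, n=1)


# -- interpretation bands ---------------------------------------------------

@pytest.mark.parametrize("bf,expected", [
    (0.3, "moderate evidence against H1"),
    (1.0, "equivocal"),
    (153.33, "extreme evidence for H1"),
    (2.0, "anecdotal evidence for H1"),
    (15.0, "strong evidence for H1"),
    (45.0, "very strong evidence for H1"),
    (0.02, "very strong evidence against H1"),
])
def test_interpret_bf_bands(bf, expected):
    assert interpret_bf(bf) == expected


def test_interpret_bf_rejects_nonpositive():
    with pytest.raises(ValueError):
        interpret_bf(0.0)


# -- rank transform ---------------------------------------------------------

def test_rank_transform_examples():
    np.testing.assert_array_equal(rank_transform([10, 20, 30]), [1, 2, 3])
    np.testing.assert_array_equal(rank_transform([5, 5, 7]), [1.5, 1.5, 3])
    out = rank_transform([3.0, np.nan, 1.0])
    assert np.isnan(out[1]) and list(out[[0, 2]]) == [2.0, 1.0]


@settings(deadline=None, max_examples=30)
@given(st.lists(st.integers(-100, 100), min_size=2, max_size=20, unique=True))
def test_rank_transform_invariant_under_monotone_maps(values):
    x = np.asarray(values, dtype=float)
    np.testing.assert_array_equal(rank_transform(x),
                                  rank_transform(np.exp(x / 50.0)))


# -- linear-model BF --------------------------------------------------------

def make_study(d, seed, n=16, missing=False):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n):
        offset = rng.normal(0, 1)
        for j, cond in enumerate(("background", "blue-dim", "yellow-bright")):
            if missing and p == 0 and j == 2:
                continue
            rows.append((f"P{p:02d}", "M" if p % 2 else "F", cond,
                         offset + d * (j - 1) + rng.normal(0, 1)))
    return pd.DataFrame(rows, columns=["participant", "gender", "condition",
                                       "y"])


def test_lm_bf_null_data_favour_h0():
    bfs = [lm_bf(make_study(0.0, s), "y", fixed=["condition"],
                 random=["participant", "gender"], draws=4000, seed=s).bf10
           for s in range(24)]
    assert np.median(bfs) < 1


def test_lm_bf_strong_effect_detected():
    bfs = [lm_bf(make_study(1.2, s), "y", fixed=["condition"],
                 random=["participant", "gender"], draws=4000, seed=s).bf10
           for s in range(24)]
    assert np.median(bfs) > 10


def test_lm_bf_handles_missing_cells_without_dropping_participants():
    result = lm_bf(make_study(0.8, 3, missing=True), "y", fixed=["condition"],
                   random=["participant", "gender"], draws=4000, seed=3)
    assert result.bf10 > 0  # all remaining rows used, P00 retained


def test_lm_bf_agrees_with_paired_ttest_on_two_conditions(rng):
    """Balanced two-condition data: the linear-model BF tracks the JZS
    paired BF within the documented approximation margin."""
    n = 16
    rows = []
    diffs = []
    for p in range(n):
        base = rng.normal(0, 1)
        d = rng.normal(0.9, 1.0)
        diffs.append(d)
        rows.append((f"P{p:02d}", "a", base - d / 2))
        rows.append((f"P{p:02d}", "b", base + d / 2))
    frame = pd.DataFrame(rows, columns=["participant", "condition", "y"])
    lm = lm_bf(frame, "y", fixed=["condition"], random=["participant"],
               draws=60_000, seed=7)
    tt = jzs_ttest_bf(data=np.asarray(diffs))
    assert np.log(lm.bf10) == pytest.approx(np.log(tt.bf10), abs=np.log(1.2))


def test_lm_bf_rank_option_runs():
    result = lm_bf(make_study(1.0, 5), "y", fixed=["condition"],
                   random=["participant"], rank=True, draws=4000, seed=5)
    assert result.bf10 > 0


def test_lm_bf_single_condition_rejected():
    frame = make_study(0.0, 1)
    frame = frame[frame["condition"] == "background"]
    with pytest.raises(ValueError):
        LinearModelBF(frame, "y", fixed=["condition"], random=["participant"])


def test_lm_bf_laplace_method_close_to_monte_carlo():
    frame = make_study(1.0, 9)
    mc = lm_bf(frame, "y", fixed=["condition"], random=["participant"],
               draws=40_000, seed=2)
    lap = lm_bf(frame, "y", fixed=["condition"], random=["participant"],
                method="laplace")
    assert lap.method == "laplace"
    assert np.log(lap.bf10) == pytest.approx(np.log(mc.bf10), abs=np.log(1.6))


# -- sequential design ------------------------------------------------------

def test_unreachable_boundary_all_inconclusive():
    r = sequential_design_sim(0.0, boundary=1e6, replicates=400, seed=1)
    assert r.inconclusive == 1.0


def test_same_seed_bit_reproducible():
    a = sequential_design_sim(0.5, replicates=500, seed=9)
    b = sequential_design_sim(0.5, replicates=500, seed=9)
    assert a == b


def test_evidence_rate_monotone_in_effect_size():
    rates = [sequential_design_sim(d, replicates=2000, seed=4).evidence_h1
             for d in (0.2, 0.5, 0.8)]
    assert rates[0] < rates[1] < rates[2]


def test_invalid_bounds_rejected():
    with pytest.raises(ValueError):
        sequential_design_sim(0.5, n_min=10, n_max=4)
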