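import numpy as np
import pytest

from chronolight.outcomes import (Hypnogram, PVTSession, alpha_theta_ratio,
                                  band_power, segment_cycles,
                                  sleep_efficiency, sleep_latency_10min,
                                  summarize_pvt, swa_deciles,
                                  visual_comfort_score, ALPHA_BAND, THETA_BAND,
                                  SWA_BAND, KDT_ELECTRODES, SWA_ELECTRODES)


def session(rts):
    return PVTSession("P01", "background", 1, 30.0, np.asarray(rts, float))


# -- PVT --------------------------------------------------------------------

def test_pvt_hand_computed_example():
    rts = [90.0] + [150.0 + 100.0 * k for k in range(10)]
    s = summarize_pvt(session(rts))
    assert s.n_valid == 10
    assert s.median_ms == 600.0
    assert s.fastest_decile_ms == 150.0
    assert s.slowest_decile_ms == 1050.0


def test_pvt_all_equal_trials():
    s = summarize_pvt(session([300.0] * 25))
    assert s.median_ms == s.fastest_decile_ms == s.slowest_decile_ms == 300.0


def test_pvt_no_valid_trials_errors():
    with pytest.raises(ValueError, match="valid"):
        summarize_pvt(session([50.0, 80.0, 99.0]))


def test_pvt_few_valid_trials_median_only():
    s = summarize_pvt(session([120.0, 150.0, 180.0]))
    assert s.n_valid == 3 and s.median_ms == 150.0
    assert s.fastest_decile_ms is None and s.slowest_decile_ms is None


def test_pvt_invariant_to_trial_order(rng):
    rts = rng.uniform(80, 900, size=87)
    a = summarize_pvt(session(rts))
    b = summarize_pvt(session(rng.permutation(rts)))
    assert a == b


# -- visual comfort ---------------------------------------------------------

def test_comfort_examples():
    assert visual_comfort_score([3, 3, 3, 3]) == 3.0
    assert visual_comfort_score([1, 2, 3, 4]) == 2.5
    assert visual_comfort_score([1, 2, 3, 4], reverse_items=(2,)) == 2.5
    with pytest.raises(ValueError):
        visual_comfort_score([1, 2, 3])
    with pytest.raises(ValueError):
        visual_comfort_score([0, 2, 3, 4])


# -- band power -------------------------------------------------------------

def test_pure_tone_parseval():
    rate, amp = 250.0, 2.0
    t = np.arange(int(20 * rate)) / rate
    x = amp * np.sin(2 * np.pi * 10.0 * t)
    assert band_power(x, rate, ALPHA_BAND) == pytest.approx(amp ** 2 / 2,
                                                            rel=0.01)
    assert band_power(x, rate, THETA_BAND) < 1e-6


def test_zero_signal_zero_power():
    assert band_power(np.zeros(1000), 100.0, ALPHA_BAND) == 0.0


def test_band_outside_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        band_power(np.zeros(1000), 20.0, (8.0, 12.0))


def test_white_noise_power_proportional_to_bin_count(rng):
    rate = 100.0
    x = rng.normal(0, 1, size=int(2000 * rate))  # 1000 two-second bins
    p_alpha = band_power(x, rate, ALPHA_BAND)    # 9 half-Hz bins
    p_theta = band_power(x, rate, THETA_BAND)    # 7 half-Hz bins
    assert p_alpha / p_theta == pytest.approx(9.0 / 7.0, rel=0.05)


def test_band_power_additive_over_disjoint_bands(rng):
    rate = 100.0
    x = rng.normal(0, 1, size=int(400 * rate))
    total = band_power(x, rate, (0.5, 49.5))
    parts = (band_power(x, rate, (0.5, 10.0))
             + band_power(x, rate, (10.5, 49.5)))
    assert parts == pytest.approx(total, rel=1e-9)
    assert total == pytest.approx(np.var(x), rel=0.05)  # Parseval


# -- alpha/theta ratio ------------------------------------------------------

def synth_kdt(rate=250.0, dur=20.0, alpha_amp=2.0, theta_amp=1.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(dur * rate)) / rate
    out = {}
    for ch in KDT_ELECTRODES:
        out[ch] = (alpha_amp * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 6))
                   + theta_amp * np.sin(2 * np.pi * 5.5 * t + rng.uniform(0, 6)))
    return out


def test_alpha_theta_ratio_amplitude_squares():
    """Alpha amplitude 2× theta ⇒ power ratio ≈ 4."""
    r = alpha_theta_ratio(synth_kdt(), 250.0)
    assert r.alpha_theta_ratio == pytest.approx(4.0, rel=0.02)
    assert r.theta_alpha_ratio == pytest.approx(0.25, rel=0.02)


def test_alpha_theta_identical_channels_match_single_channel():
    eeg = synth_kdt()
    single = eeg["P3"]
    same = {ch: single for ch in KDT_ELECTRODES}
    r = alpha_theta_ratio(same, 250.0)
    expected = (band_power(single, 250.0, ALPHA_BAND)
                / band_power(single, 250.0, THETA_BAND))
    assert r.alpha_theta_ratio == pytest.approx(expected, rel=1e-12)


def test_alpha_theta_missing_electrode_listed():
    eeg = synth_kdt()
    del eeg["Oz"]
    with pytest.raises(ValueError, match="Oz"):
        alpha_theta_ratio(eeg, 250.0)


def test_zero_theta_flagged():
    eeg = {ch: np.zeros(5000) for ch in KDT_ELECTRODES}
    with pytest.raises(ZeroDivisionError):
        alpha_theta_ratio(eeg, 250.0)


# -- sleep latency ----------------------------------------------------------

def test_slat_simple_example():
    hyp = Hypnogram(("W",) * 10 + ("N2",) * 20)
    assert sleep_latency_10min(hyp) == 5.0


def test_slat_skips_interrupted_run():
    hyp = Hypnogram(("N2",) * 19 + ("W",) + ("N2",) * 20)
    assert sleep_latency_10min(hyp) == 10.0


def test_slat_all_wake_undefined():
    assert sleep_latency_10min(Hypnogram(("W",) * 40)) is None


def brute_force_slat(stages, run=20):
    asleep = [s != "W" for s in stages]
    for start in range(len(stages) - run + 1):
        if all(asleep[start:start + run]):
            return start * 0.5
    return None


def test_slat_matches_exhaustive_scan(rng):
    for _ in range(200):
        stages = tuple(rng.choice(["W", "N1", "N2", "N3", "REM"], size=60,
                                  p=[0.3, 0.1, 0.3, 0.2, 0.1]))
        assert sleep_latency_10min(Hypnogram(stages)) == brute_force_slat(stages)


# -- cycles -----------------------------------------------------------------

def test_textbook_cycle():
    stages = (("W",) * 10 + ("N1",) * 4 + ("N2",) * 60 + ("N3",) * 60
              + ("N2",) * 30 + ("REM",) * 20 + ("N2",) * 40)
    cycles = segment_cycles(Hypnogram(stages))
    first = cycles[0]
    assert not first.merged and not first.open_cycle
    assert first.nrem_intervals == ((10, 164),)
    assert first.rem_interval == (164, 184)


def test_short_rem_latency_merges_first_two_nrem_parts():
    stages = (("W",) * 4 + ("N2",) * 40            # 20 min NREM (< 30 min)
              + ("REM",) * 12                      # first REM
              + ("N2",) * 80 + ("REM",) * 14       # second cycle
              + ("N2",) * 40)
    cycles = segment_cycles(Hypnogram(stages))
    first = cycles[0]
    assert first.merged
    assert first.nrem_intervals == ((4, 44), (56, 136))
    assert first.rem_interval == (136, 150)


def test_no_rem_yields_open_cycle():
    cycles = segment_cycles(Hypnogram(("W",) * 6 + ("N2",) * 100))
    assert len(cycles) == 1 and cycles[0].open_cycle


def test_short_first_rem_episode_still_ends_cycle():
    """First REM episode is exempt from the 5-min minimum."""
    stages = ("N2",) * 70 + ("REM",) * 4 + ("N2",) * 80 + ("REM",) * 12
    cycles = segment_cycles(Hypnogram(stages))
    assert cycles[0].rem_interval == (70, 74)
    # later REM runs must reach 5 min: a 4-epoch run would not qualify
    stages2 = ("N2",) * 70 + ("REM",) * 12 + ("N2",) * 80 + ("REM",) * 4
    cycles2 = segment_cycles(Hypnogram(stages2))
    assert len(cycles2) == 1


def test_too_short_nrem_extends_to_next_rem():
    stages = (("N2",) * 70 + ("REM",) * 12        # cycle 1 (35 min NREM)
              + ("N2",) * 20 + ("REM",) * 12      # only 10 min NREM: skip
              + ("N2",) * 60 + ("REM",) * 12)
    cycles = segment_cycles(Hypnogram(stages))
    assert cycles[0].rem_interval == (70, 82)
    assert cycles[1].nrem_intervals == ((82, 174),)
    assert cycles[1].rem_interval == (174, 186)


# -- sleep efficiency -------------------------------------------------------

def test_sleep_efficiency_values():
    assert sleep_efficiency(Hypnogram(("N2",) * 100)) == (1.0, False)
    seff, flag = sleep_efficiency(Hypnogram(("W", "N2") * 50))
    assert seff == 0.5 and flag
    seff, flag = sleep_efficiency(Hypnogram(("N2",) * 69 + ("W",) * 31))
    assert seff == pytest.approx(0.69) and flag


def test_sleep_efficiency_zero_time_in_bed():
    with pytest.raises(ValueError):
        sleep_efficiency(Hypnogram(("N2",) * 10), lights_on_epoch=0)


# -- SWA deciles ------------------------------------------------------------

def make_cycle_record(nrem_epochs=100, rem_epochs=20, rate=128.0,
                      decay=None, seed=0):
    stages = ("N2",) * nrem_epochs + ("REM",) * rem_epochs
    hyp = Hypnogram(stages)
    cycle = segment_cycles(hyp)[0]
    n = int(len(stages) * 30 * rate)
    t = np.arange(n) / rate
    amp = np.ones(n) if decay is None else np.exp(-t / decay)
    eeg = {ch: amp * np.sin(2 * np.pi * 1.5 * t + i)
           for i, ch in enumerate(SWA_ELECTRODES)}
    return eeg, hyp, cycle


def test_swa_stationary_deciles_equal():
    eeg, hyp, cycle = make_cycle_record()
    profile = swa_deciles(eeg, 128.0, cycle, hyp)
    np.testing.assert_allclose(profile.nrem_deciles,
                               profile.nrem_deciles[0], rtol=1e-2)
    assert profile.as_vector().shape == (20,)


def test_swa_decaying_amplitude_monotone_deciles():
    eeg, hyp, cycle = make_cycle_record(decay=1200.0)
    profile = swa_deciles(eeg, 128.0, cycle, hyp)
    assert np.all(np.diff(profile.nrem_deciles) < 0)


def test_swa_decile_bin_arithmetic():
    """A pure unit 2-Hz tone gives every decile power A²/2 = 0.5; a 1200-s
    NREM part splits into ten 120-s deciles of 60 two-second bins."""
    rate = 128.0
    hyp = Hypnogram(("N2",) * 40 + ("REM",) * 10)
    cycle = segment_cycles(hyp)[0]
    assert cycle.nrem_epochs == 40
    n = int(50 * 30 * rate)
    t = np.arange(n) / rate
    eeg = {ch: np.sin(2 * np.pi * 2.0 * t) for ch in SWA_ELECTRODES}
    profile = swa_deciles(eeg, rate, cycle, hyp)
    np.testing.assert_allclose(profile.nrem_deciles, 0.5, rtol=0.02)
    np.testing.assert_allclose(profile.rem_deciles, 0.5, rtol=0.02)


def test_swa_part_too_short_rejected():
    """With 15-s epochs a one-epoch REM part is under the 20-s minimum."""
    from chronolight.sleep import SleepCycle

    rate = 128.0
    hyp = Hypnogram(("N2",) * 60 + ("REM",) * 1, epoch_s=15.0)
    cycle = SleepCycle(((0, 60),), (60, 61))
    eeg = {ch: np.zeros(int(61 * 15 * rate)) for ch in SWA_ELECTRODES}
    with pytest.raises(ValueError, match="20 s"):
        swa_deciles(eeg, rate, cycle, hyp)
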