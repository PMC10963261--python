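"""Synthetic circadian light-exposure study generator.

Emulates the statistical structure of the study's deposited data so every
pipeline stage can be exercised without any download: 16 participants
(balanced sexes) × 3 light conditions × 2 evenings of half-hourly salivary
melatonin with a hockey-stick rise and condition-specific evening-2 phase
delays, melatonin suppression during the evening-1 exposure window,
ex-Gaussian PVT reaction times, ordinal KSS and comfort ratings,
band-limited KDT EEG, staged sleep (semi-Markov hypnograms with a
controllable REM latency) and frontal sleep EEG with decaying slow-wave
activity.  Ground truth (true DLMOs, shifts, band powers, cycle spans) is
stored alongside for recovery tests.

Defaults are the study's own conditions: per-condition mean phase delays of
52.0 / 41.94 / 33.8 min (background / blue-dim / yellow-bright), PVT median
targets near 384.4 / 399.8 / 395.5 ms, KSS latent means 6.19 / 5.47 / 5.56.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import (CONDITIONS, SALIVA_TICKS_MIN, KDT_TIMES_MIN,
                       EXPOSURE_START_MIN, EXPOSURE_DURATION_MIN)
from .sleep import Hypnogram, segment_cycles
from .eeg import KDT_ELECTRODES, SWA_ELECTRODES

__all__ = ["StudyConfig", "StudyDataset", "generate_study", "write_dataset"]


@dataclass
class StudyConfig:
    """Parameters of the synthetic study (defaults = the study conditions)."""

    n_participants: int = 16          # balanced sexes, 8 + 8
    conditions: tuple = CONDITIONS

    # circadian phase
    phase_delay_min: dict = field(default_factory=lambda: {
        "background": 52.0, "blue-dim": 41.94, "yellow-bright": 33.8})
    phase_delay_sd_min: float = 25.0  # between-participant SD of the shift
    dlmo_mean_min: float = -120.0     # evening-1 onset relative to HBT
    dlmo_sd_min: float = 30.0
    visit_jitter_sd_min: float = 5.0  # evening-1 onset jitter across visits

    # melatonin curve
    baseline_range_pg_ml: tuple = (1.0, 3.0)
    baseline_slope: float = 0.0
    rise_coeff_range: tuple = (0.002, 0.006)   # pg ml⁻¹ min⁻²
    lognormal_sigma: float = 0.15              # multiplicative assay noise
    suppression_factor: float = 0.4            # fractional dip in the window
    suppression_by_condition: dict | None = None
    suppression_ramp_min: float = 10.0

    # vigilance / sleepiness / comfort
    include_behavior: bool = True     # PVT/KSS/comfort streams
    pvt_median_ms: dict = field(default_factory=lambda: {
        "background": 384.4, "blue-dim": 399.8, "yellow-bright": 395.5})
    pvt_sigma_ms: float = 30.0
    pvt_tau_ms: float = 60.0
    pvt_participant_sd_ms: float = 25.0
    pvt_trials: int = 90
    kss_mean: dict = field(default_factory=lambda: {
        "background": 6.19, "blue-dim": 5.47, "yellow-bright": 5.56})
    kss_sd: float = 1.6
    comfort_mean: dict = field(default_factory=lambda: {
        "background": 3.3, "blue-dim": 3.4, "yellow-bright": 3.5})
    comfort_sd: float = 0.55

    # KDT EEG
    include_kdt_eeg: bool = True
    eeg_rate_hz: float = 500.0
    kdt_duration_s: float = 180.0
    alpha_amp_uv: float = 20.0
    theta_amp_uv: float = 10.0
    eeg_noise_uv: float = 10.0

    # sleep
    include_sleep_eeg: bool = True
    sleep_eeg_rate_hz: float = 128.0  # SWA needs only the 0.5-4.5 Hz band
    sleep_epochs: int = 720           # 6-h opportunity at 30-s epochs
    sleep_latency_mean_min: float = 12.0
    rem_latency_mean_min: float = 70.0
    rem_latency_sd_min: float = 15.0
    swa_amp_uv: float = 40.0
    swa_decay_min: float = 45.0       # exponential decay of delta amplitude
    swa_rem_fraction: float = 0.15

    def __post_init__(self):
        if len(self.conditions) != 3:
            raise ValueError("the study design has exactly three conditions")
        for name in ("phase_delay_sd_min", "lognormal_sigma", "pvt_sigma_ms",
                     "pvt_tau_ms", "kss_sd", "comfort_sd", "eeg_noise_uv",
                     "rem_latency_sd_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.suppression_factor < 1:
            raise ValueError("suppression factor must be in [0, 1)")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


@dataclass
class StudyDataset:
    """All generated tables plus the ground truth they were drawn from."""

    melatonin: pd.DataFrame
    pvt: pd.DataFrame
    kss: pd.DataFrame
    comfort: pd.DataFrame
    hypnograms: dict              # (participant, condition) -> Hypnogram
    kdt_eeg: dict                 # (participant, condition, time_min) -> {ch: µV}
    sleep_eeg: dict               # (participant, condition) -> {ch: µV}
    ground_truth: dict
    config: StudyConfig
    seed: int


def _exgauss_mu_for_median(median: float, sigma: float, tau: float) -> float:
    """Location of an ex-Gaussian with the requested median."""
    offset = stats.exponnorm.ppf(0.5, K=tau / sigma, loc=0.0, scale=sigma)
    return median - float(offset)


def _melatonin_curve(t, a, b, c, t0):
    return a + b * t + c * np.clip(t - t0, 0.0, None) ** 2


def _suppression_envelope(t, factor, ramp):
    """Multiplicative dip (1 → 1−factor → 1) over the exposure window."""
    start, end = EXPOSURE_START_MIN, EXPOSURE_START_MIN + EXPOSURE_DURATION_MIN
    depth = np.zeros_like(t, dtype=float)
    inside = (t >= start) & (t <= end)
    depth[inside] = 1.0
    rise = (t >= start - ramp) & (t < start)
    depth[rise] = (t[rise] - (start - ramp)) / ramp
    fall = (t > end) & (t <= end + ramp)
    depth[fall] = ((end + ramp) - t[fall]) / ramp
    return 1.0 - factor * depth


def _make_hypnogram(rng, config: StudyConfig) -> tuple[Hypnogram, dict]:
    """Semi-Markov-style staged night; returns the hypnogram + truth info."""
    epochs_per_min = 2
    latency = max(1, int(round(rng.normal(config.sleep_latency_mean_min, 4.0)
                               * epochs_per_min)))
    rem_latency = max(20.0, rng.normal(config.rem_latency_mean_min,
                                       config.rem_latency_sd_min))
    stages: list[str] = ["W"] * latency
    truth = {"sleep_onset_epoch": latency}
    n1 = int(rng.integers(2, 6))
    stages += ["N1"] * n1
    # first NREM episode fills until REM latency (from sleep onset)
    first_rem_start = latency + int(round(rem_latency * epochs_per_min))
    n3 = max(4, int(0.4 * (first_rem_start - len(stages))))
    while len(stages) < first_rem_start:
        remaining = first_rem_start - len(stages)
        if remaining > n3 + 6:
            stages += ["N2"] * min(6, remaining - n3)
        elif remaining > n3:
            stages += ["N2"] * (remaining - n3)
        else:
            stages += ["N3"] * remaining
    rem1 = max(4, int(rng.integers(8, 16)))
    stages += ["REM"] * rem1
    truth["rem1"] = (first_rem_start, first_rem_start + rem1)
    # subsequent cycles: ~80-min NREM + ~20-min REM until the record is full
    while len(stages) < config.sleep_epochs:
        nrem = int(rng.normal(160, 20))
        stages += (["N2"] * (nrem // 2) + ["N3"] * (nrem // 4)
                   + ["N2"] * (nrem - nrem // 2 - nrem // 4))
        stages += ["REM"] * int(rng.normal(30, 6))
    stages = stages[:config.sleep_epochs]
    return Hypnogram(tuple(stages)), truth


def _sleep_eeg_for(hypnogram: Hypnogram, rng, config: StudyConfig) -> dict:
    """Frontal channels covering the whole record, µV, float32.

    Delta-band oscillation whose amplitude decays exponentially through
    NREM sleep and collapses during REM/wake, on top of broadband noise.
    """
    rate = config.sleep_eeg_rate_hz
    n = int(hypnogram.n_epochs * hypnogram.epoch_s * rate)
    t = np.arange(n) / rate
    epoch_of_sample = (t / hypnogram.epoch_s).astype(int)
    stage_arr = np.array(hypnogram.stages)
    in_nrem = np.isin(stage_arr, ("N1", "N2", "N3"))[epoch_of_sample]
    in_rem = (stage_arr == "REM")[epoch_of_sample]
    decay = np.exp(-t / (config.swa_decay_min * 60.0))
    amp = np.where(in_nrem, config.swa_amp_uv * decay,
                   np.where(in_rem, config.swa_rem_fraction
                            * config.swa_amp_uv * decay, 2.0))
    out = {}
    for ch in SWA_ELECTRODES:
        phase = rng.uniform(0, 2 * np.pi)
        delta = amp * np.sin(2 * np.pi * 1.5 * t + phase)
        noise = rng.normal(0.0, 3.0, size=n)
        out[ch] = (delta + noise).astype(np.float32)
    return out


def _kdt_segment(rng, config: StudyConfig) -> dict:
    n = int(config.kdt_duration_s * config.eeg_rate_hz)
    t = np.arange(n) / config.eeg_rate_hz
    out = {}
    for ch in KDT_ELECTRODES:
        alpha = config.alpha_amp_uv * np.sin(
            2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        theta = config.theta_amp_uv * np.sin(
            2 * np.pi * 5.5 * t + rng.uniform(0, 2 * np.pi))
        noise = rng.normal(0.0, config.eeg_noise_uv, size=n)
        out[ch] = (alpha + theta + noise).astype(np.float32)
    return out


def generate_study(config: StudyConfig | None = None, seed: int | None = None
                   ) -> StudyDataset:
    """Draw one complete synthetic study.

    ``seed`` is mandatory: the same seed and config reproduce the dataset
    bit for bit.
    """
    config = config or StudyConfig()
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    root = np.random.default_rng(np.random.SeedSequence(seed))

    ticks = np.array(SALIVA_TICKS_MIN, dtype=float)
    mel_rows, pvt_rows, kss_rows, comfort_rows = [], [], [], []
    hypnograms, kdt_eeg, sleep_eeg = {}, {}, {}
    truth = {"participants": {}, "records": {}}

    mu_by_cond = {c: _exgauss_mu_for_median(config.pvt_median_ms[c],
                                            config.pvt_sigma_ms,
                                            config.pvt_tau_ms)
                  for c in config.conditions}
    suppression = config.suppression_by_condition or {
        c: config.suppression_factor for c in config.conditions}

    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        sex = "M" if p % 2 == 0 else "F"
        prng = np.random.default_rng(np.random.SeedSequence((seed, p)))
        base_t0 = prng.normal(config.dlmo_mean_min, config.dlmo_sd_min)
        baseline = prng.uniform(*config.baseline_range_pg_ml)
        rise = prng.uniform(*config.rise_coeff_range)
        pvt_offset = prng.normal(0.0, config.pvt_participant_sd_ms)
        kss_offset = prng.normal(0.0, 0.8)
        truth["participants"][pid] = {
            "sex": sex, "dlmo_evening1_min": base_t0,
            "baseline_pg_ml": baseline, "rise_coeff": rise}

        for cond in config.conditions:
            key = (pid, cond)
            t0_e1 = base_t0 + prng.normal(0.0, config.visit_jitter_sd_min)
            delay = (config.phase_delay_min[cond]
                     + prng.normal(0.0, config.phase_delay_sd_min))
            t0_e2 = t0_e1 + delay
            rec = {"t0_evening1": t0_e1, "t0_evening2": t0_e2,
                   "true_delay_min": delay}

            for evening, t0 in ((1, t0_e1), (2, t0_e2)):
                clean = _melatonin_curve(ticks, baseline,
                                         config.baseline_slope, rise, t0)
                if evening == 1:
                    clean = clean * _suppression_envelope(
                        ticks, suppression[cond], config.suppression_ramp_min)
                noisy = clean * np.exp(prng.normal(
                    0.0, config.lognormal_sigma, size=ticks.size))
                for tt, cc in zip(ticks, noisy):
                    mel_rows.append((pid, cond, evening, tt, max(cc, 0.0)))

                if not config.include_behavior:
                    continue
                mu = mu_by_cond[cond] + pvt_offset
                for tt in ticks:
                    rts = stats.exponnorm.rvs(
                        config.pvt_tau_ms / config.pvt_sigma_ms, loc=mu,
                        scale=config.pvt_sigma_ms,
                        size=config.pvt_trials, random_state=prng)
                    rts = np.clip(rts, 60.0, None)
                    for trial, rt in enumerate(rts):
                        pvt_rows.append((pid, cond, evening, tt, trial, rt))
                    kss = np.clip(np.rint(prng.normal(
                        config.kss_mean[cond] + kss_offset, config.kss_sd)),
                        1, 9)
                    kss_rows.append((pid, cond, evening, tt, int(kss)))
                    items = np.clip(np.rint(prng.normal(
                        config.comfort_mean[cond], config.comfort_sd, size=4)),
                        1, 5).astype(int)
                    comfort_rows.append((pid, cond, evening, tt, *items))

            if config.include_kdt_eeg:
                for kdt_time in KDT_TIMES_MIN:
                    kdt_eeg[(pid, cond, float(kdt_time))] = _kdt_segment(
                        prng, config)
                rec["true_alpha_power"] = config.alpha_amp_uv ** 2 / 2.0
                rec["true_theta_power"] = config.theta_amp_uv ** 2 / 2.0

            hyp, hyp_truth = _make_hypnogram(prng, config)
            hypnograms[key] = hyp
            rec.update(hyp_truth)
            if config.include_sleep_eeg:
                sleep_eeg[key] = _sleep_eeg_for(hyp, prng, config)
            truth["records"][key] = rec

    melatonin = pd.DataFrame(mel_rows, columns=[
        "participant", "condition", "evening", "time_min_rel_hbt",
        "concentration_pg_ml"])
    pvt = pd.DataFrame(pvt_rows, columns=[
        "participant", "condition", "evening", "time_min_rel_hbt",
        "trial", "rt_ms"])
    kss = pd.DataFrame(kss_rows, columns=[
        "participant", "condition", "evening", "time_min_rel_hbt", "kss"])
    comfort = pd.DataFrame(comfort_rows, columns=[
        "participant", "condition", "evening", "time_min_rel_hbt",
        "pleasantness", "brightness", "glare", "colour_temperature"])
    return StudyDataset(melatonin, pvt, kss, comfort, hypnograms, kdt_eeg,
                        sleep_eeg, truth, config, seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_dataset(dataset: StudyDataset, directory) -> dict:
    """Write the dataset in the formats the analysis modules read.

    Tabular streams go to CSV; hypnograms to one long CSV; EEG arrays to
    compressed ``.npz``.  Returns (and writes) a manifest with SHA-256
    checksums of every file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []

    for name in ("melatonin", "pvt", "kss", "comfort"):
        path = directory / f"{name}.csv"
        getattr(dataset, name).to_csv(path, index=False)
        files.append(path)

    participants = pd.DataFrame(
        [(pid, info["sex"]) for pid, info in
         dataset.ground_truth["participants"].items()],
        columns=["participant", "sex"])
    path = directory / "participants.csv"
    participants.to_csv(path, index=False)
    files.append(path)

    rows = []
    for (pid, cond), hyp in dataset.hypnograms.items():
        for i, stage in enumerate(hyp.stages):
            rows.append((pid, cond, i, stage))
    path = directory / "hypnograms.csv"
    pd.DataFrame(rows, columns=["participant", "condition", "epoch", "stage"]
                 ).to_csv(path, index=False)
    files.append(path)

    if dataset.kdt_eeg:
        arrays = {f"{pid}|{cond}|{time:g}|{ch}": arr
                  for (pid, cond, time), chans in dataset.kdt_eeg.items()
                  for ch, arr in chans.items()}
        path = directory / "kdt_eeg.npz"
        np.savez_compressed(path, **arrays)
        files.append(path)
    if dataset.sleep_eeg:
        arrays = {f"{pid}|{cond}|{ch}": arr
                  for (pid, cond), chans in dataset.sleep_eeg.items()
                  for ch, arr in chans.items()}
        path = directory / "sleep_eeg.npz"
        np.savez_compressed(path, **arrays)
        files.append(path)

    manifest = {p.name: _sha256(p) for p in files}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
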