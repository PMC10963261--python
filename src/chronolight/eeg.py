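"""EEG spectral metrics: band power, alpha/theta ratio, SWA decile profiles.

All spectral estimates follow one recipe: the signal is cut into
non-overlapping 2-s bins, each bin is Hann-tapered and Fourier-transformed
(0.5-Hz resolution), and band power is the sum of bin powers over the
frequency bins inside the band, inclusive at both edges.  Powers are
variance-scaled (µV² for µV input), so band powers over disjoint bands add
up to the signal variance (Parseval, up to tapering leakage).

The alertness metric is the alpha (8–12 Hz) to theta (4–7 Hz) power ratio
averaged over parieto-occipital electrodes P3, Pz, P4, O1, Oz, O2; the
theta/alpha reciprocal is carried alongside.  Slow-wave activity (SWA,
0.5–4.5 Hz at F3, Fz, F4) is profiled over ten equal-duration deciles of
the NREM part and ten of the REM part of the first sleep cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .sleep import Hypnogram, SleepCycle

__all__ = ["BandRatioResult", "SWAProfile", "band_power", "alpha_theta_ratio",
           "swa_deciles", "ALPHA_BAND", "THETA_BAND", "SWA_BAND",
           "KDT_ELECTRODES", "SWA_ELECTRODES"]

BIN_S = 2.0                        # FFT bin length -> 0.5 Hz resolution
ALPHA_BAND = (8.0, 12.0)
THETA_BAND = (4.0, 7.0)
SWA_BAND = (0.5, 4.5)
KDT_ELECTRODES = ("P3", "Pz", "P4", "O1", "Oz", "O2")
SWA_ELECTRODES = ("F3", "Fz", "F4")


@dataclass(frozen=True)
class BandRatioResult:
    theta_power: float
    alpha_power: float
    alpha_theta_ratio: float
    theta_alpha_ratio: float
    electrodes: tuple


@dataclass(frozen=True)
class SWAProfile:
    """Mean SWA per decile: 10 NREM-part values then 10 REM-part values."""

    nrem_deciles: np.ndarray
    rem_deciles: np.ndarray

    def __post_init__(self):
        nrem = np.asarray(self.nrem_deciles, dtype=float)
        rem = np.asarray(self.rem_deciles, dtype=float)
        object.__setattr__(self, "nrem_deciles", nrem)
        object.__setattr__(self, "rem_deciles", rem)
        if nrem.shape != (10,) or rem.shape != (10,):
            raise ValueError("a SWA profile has 10 NREM and 10 REM deciles")
        if np.any(nrem < 0) or np.any(rem < 0):
            raise ValueError("powers must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.nrem_deciles, self.rem_deciles])


def band_power(segment: np.ndarray, rate_hz: float, band) -> float:
    """Mean band power of one channel over the segment's 2-s bins."""
    x = np.asarray(segment, dtype=float)
    lo, hi = band
    if hi > rate_hz / 2.0:
        raise ValueError(f"band upper edge {hi:g} Hz exceeds Nyquist "
                         f"({rate_hz / 2:g} Hz)")
    nper = int(round(BIN_S * rate_hz))
    if x.size < nper:
        raise ValueError("segment shorter than one 2-s bin")
    freqs, psd = signal.welch(x, fs=rate_hz, window="hann", nperseg=nper,
                              noverlap=0, detrend=False, scaling="density")
    df = freqs[1] - freqs[0]
    inside = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return float(np.sum(psd[inside]) * df)


def alpha_theta_ratio(eeg: dict, rate_hz: float,
                      electrodes=KDT_ELECTRODES) -> BandRatioResult:
    """Alpha/theta ratio of electrode-averaged band powers.

    ``eeg`` maps electrode name to the 1-d sample array of that channel.
    """
    missing = [e for e in electrodes if e not in eeg]
    if missing:
        raise ValueError(f"missing electrodes: {missing}")
    alpha = float(np.mean([band_power(eeg[e], rate_hz, ALPHA_BAND)
                           for e in electrodes]))
    theta = float(np.mean([band_power(eeg[e], rate_hz, THETA_BAND)
                           for e in electrodes]))
    if theta <= 0:
        raise ZeroDivisionError("theta power is zero; ratio undefined")
    return BandRatioResult(theta_power=theta, alpha_power=alpha,
                           alpha_theta_ratio=alpha / theta,
                           theta_alpha_ratio=theta / alpha,
                           electrodes=tuple(electrodes))


def _part_samples(eeg: dict, electrodes, intervals, epoch_s: float,
                  rate_hz: float, record_start_epoch: int) -> np.ndarray:
    """Concatenate the samples of the given epoch intervals, (C, N) array."""
    chunks = []
    for start, end in intervals:
        i0 = int(round((start - record_start_epoch) * epoch_s * rate_hz))
        i1 = int(round((end - record_start_epoch) * epoch_s * rate_hz))
        chunks.append(np.stack([np.asarray(eeg[e], dtype=float)[i0:i1]
                                for e in electrodes]))
    return np.concatenate(chunks, axis=1)


def swa_deciles(eeg: dict, rate_hz: float, cycle: SleepCycle,
                hypnogram: Hypnogram, electrodes=SWA_ELECTRODES,
                band=SWA_BAND, record_start_epoch: int = 0) -> SWAProfile:
    """SWA per decile of the NREM and REM parts of one cycle.

    ``eeg`` maps frontal electrode names to full-record sample arrays
    starting at ``record_start_epoch`` of the hypnogram.  Each part is split
    into ten equal-duration deciles; the decile value is the mean band power
    across 2-s bins and electrodes.
    """
    missing = [e for e in electrodes if e not in eeg]
    if missing:
        raise ValueError(f"missing electrodes: {missing}")
    if cycle.rem_interval is None:
        raise ValueError("cycle has no REM part")
    profiles = []
    for intervals in (cycle.nrem_intervals, (cycle.rem_interval,)):
        samples = _part_samples(eeg, electrodes, intervals, hypnogram.epoch_s,
                                rate_hz, record_start_epoch)
        n = samples.shape[1]
        if n < 10 * int(BIN_S * rate_hz):
            raise ValueError("cycle part shorter than 20 s; deciles undefined")
        edges = np.linspace(0, n, 11).astype(int)
        values = [
            float(np.mean([band_power(ch[edges[i]:edges[i + 1]], rate_hz, band)
                           for ch in samples]))
            for i in range(10)
        ]
        profiles.append(np.array(values))
    return SWAProfile(nrem_deciles=profiles[0], rem_deciles=profiles[1])
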