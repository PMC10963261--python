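"""Neurobehavioural and sleep outcome metrics (namespace module).

Collects the study's outcome computations in one import surface:
PVT summaries and visual comfort (:mod:`chronolight.vigilance`), hypnogram
metrics (:mod:`chronolight.sleep`) and EEG spectral metrics
(:mod:`chronolight.eeg`).
"""

from .vigilance import (PVTSession, PVTSummary, summarize_pvt,
                        visual_comfort_score)
from .sleep import (Hypnogram, SleepCycle, sleep_latency_10min, segment_cycles,
                    sleep_efficiency, STAGES)
from .eeg import (BandRatioResult, SWAProfile, band_power, alpha_theta_ratio,
                  swa_deciles, ALPHA_BAND, THETA_BAND, SWA_BAND,
                  KDT_ELECTRODES, SWA_ELECTRODES)

__all__ = [
    "PVTSession", "PVTSummary", "summarize_pvt", "visual_comfort_score",
    "Hypnogram", "SleepCycle", "sleep_latency_10min", "segment_cycles",
    "sleep_efficiency", "STAGES",
    "BandRatioResult", "SWAProfile", "band_power", "alpha_theta_ratio",
    "swa_deciles", "ALPHA_BAND", "THETA_BAND", "SWA_BAND",
    "KDT_ELECTRODES", "SWA_ELECTRODES",
]
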