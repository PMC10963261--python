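"""Evening exposure waveform and assessment schedule.

The light exposure lasts 1 h, starting 30 min after habitual bedtime (HBT).
Flickering conditions alternate 30 s of 1-Hz unipolar sinusoidal flicker
with 30 s of constant background; the background condition is constant
throughout.  Each 1-s flicker cycle starts and ends at the background
spectrum and reaches the modulation spectrum at its half-period peak:

    w(t) = w_bg + (w_mod − w_bg) · (1 − cos 2πft) / 2        (on-blocks)

Assessments: saliva, sleepiness (KSS), vigilance (PVT) and visual-comfort
ratings every 30 min from −300 to +90 min relative to HBT (14 ticks);
3-min resting EEG (KDT) at +27, +60 and +87 min; lights off at +120 min for
a 6-h sleep opportunity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExposureProtocol", "DriveTimeline", "ScheduledAssessment",
           "build_flicker_waveform", "build_evening_schedule",
           "CONDITIONS"]

CONDITIONS = ("background", "blue-dim", "yellow-bright")

#: assessment tick times in minutes relative to HBT
SALIVA_TICKS_MIN = tuple(range(-300, 91, 30))      # 14 ticks
KDT_TIMES_MIN = (27, 60, 87)
EXPOSURE_START_MIN = 30
EXPOSURE_DURATION_MIN = 60
LIGHTS_OFF_MIN = 120
SLEEP_OPPORTUNITY_MIN = 360
MORNING_SALIVA_OFFSETS_MIN = (0, 30, 60, 90, 120)  # from wake-up


@dataclass(frozen=True)
class ExposureProtocol:
    """Timing of the nocturnal light exposure."""

    condition: str = "background"
    start_offset_min: float = EXPOSURE_START_MIN
    duration_min: float = EXPOSURE_DURATION_MIN
    flicker_frequency_hz: float = 1.0
    on_block_s: float = 30.0
    off_block_s: float = 30.0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        pair = self.on_block_s + self.off_block_s
        if (self.duration_min * 60.0) % pair != 0:
            raise ValueError("exposure duration must be a whole number of "
                             "on/off block pairs")

    @property
    def n_cycles(self) -> int:
        return int(self.duration_min * 60.0 // (self.on_block_s + self.off_block_s))


@dataclass(frozen=True)
class DriveTimeline:
    """Sampled per-primary drive weights across the exposure."""

    times_s: np.ndarray           # from exposure start
    weights: np.ndarray           # (n_samples, n_primaries) in [0, 1]
    rate_hz: float

    def to_frame(self, levels: int | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"t_s": self.times_s})
        for j in range(self.weights.shape[1]):
            col = self.weights[:, j]
            if levels:
                col = np.rint(col * (levels - 1)).astype(int)
            out[f"primary_{j}"] = col
        return out


@dataclass(frozen=True)
class ScheduledAssessment:
    kind: str                     # saliva | KSS | PVT | comfort | KDT | ...
    time_min: float               # relative to HBT


def build_flicker_waveform(protocol: ExposureProtocol, w_bg, w_mod,
                           rate_hz: float = 100.0) -> DriveTimeline:
    """Sample the drive-weight trajectory of the whole exposure.

    The background condition (or ``w_mod == w_bg``) yields a constant
    timeline at the background weights.
    """
    if rate_hz < 10:
        raise ValueError("sampling rate must be at least 10 Hz")
    w_bg = np.asarray(w_bg, dtype=float)
    w_mod = np.asarray(w_mod, dtype=float)
    if w_bg.shape != w_mod.shape:
        raise ValueError("background and modulation weight vectors differ in size")

    duration_s = protocol.duration_min * 60.0
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    cycle = protocol.on_block_s + protocol.off_block_s
    t_in_cycle = np.mod(t, cycle)
    on = t_in_cycle < protocol.on_block_s
    if protocol.condition == "background":
        envelope = np.zeros(n)
    else:
        phase = 2.0 * np.pi * protocol.flicker_frequency_hz * t_in_cycle
        envelope = np.where(on, (1.0 - np.cos(phase)) / 2.0, 0.0)
    weights = w_bg[None, :] + envelope[:, None] * (w_mod - w_bg)[None, :]
    return DriveTimeline(times_s=t, weights=weights, rate_hz=rate_hz)


def build_evening_schedule(hbt_clock_time: str | None = None,
                           condition: str = "background"):
    """Full evening assessment schedule, in minutes relative to HBT.

    When ``hbt_clock_time`` (\"HH:MM\") is given, the exported frame also
    carries wall-clock times.
    """
    events: list[ScheduledAssessment] = []
    for tick in SALIVA_TICKS_MIN:
        for kind in ("saliva", "KSS", "PVT", "comfort"):
            events.append(ScheduledAssessment(kind, float(tick)))
    for t in KDT_TIMES_MIN:
        events.append(ScheduledAssessment("KDT", float(t)))
    events.append(ScheduledAssessment("exposure_start", float(EXPOSURE_START_MIN)))
    events.append(ScheduledAssessment(
        "exposure_end", float(EXPOSURE_START_MIN + EXPOSURE_DURATION_MIN)))
    events.append(ScheduledAssessment("lights_off", float(LIGHTS_OFF_MIN)))
    events.append(ScheduledAssessment(
        "sleep_opportunity_end", float(LIGHTS_OFF_MIN + SLEEP_OPPORTUNITY_MIN)))
    wake = LIGHTS_OFF_MIN + SLEEP_OPPORTUNITY_MIN
    for off in MORNING_SALIVA_OFFSETS_MIN:
        events.append(ScheduledAssessment("saliva_morning", float(wake + off)))
        events.append(ScheduledAssessment("KSS_morning", float(wake + off)))
    events.sort(key=lambda e: (e.time_min, e.kind))
    return events


def schedule_frame(events, hbt_clock_time: str | None = None) -> pd.DataFrame:
    """Schedule as a data frame, optionally with wall-clock times."""
    frame = pd.DataFrame({"kind": [e.kind for e in events],
                          "minutes_rel_HBT": [e.time_min for e in events]})
    if hbt_clock_time:
        hh, mm = map(int, hbt_clock_time.split(":"))
        base = hh * 60 + mm
        clock = (base + frame["minutes_rel_HBT"]) % (24 * 60)
        frame["clock_time"] = [f"{int(c) // 60:02d}:{int(c) % 60:02d}"
                               for c in clock]
    return frame
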