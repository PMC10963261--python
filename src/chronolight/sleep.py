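"""Hypnogram-derived sleep metrics: onset latency, cycles, efficiency.

Hypnograms are 30-s epoch stage sequences over the AASM alphabet
{W, N1, N2, N3, REM}; N1 counts as sleep.  Sleep-onset latency is measured
to the first run of 10 min (20 epochs) of continuous sleep from lights off.
Sleep cycles follow the classic segmentation — a NREM episode of at least
15 min ending at a REM episode of at least 5 min, the first REM episode
exempt from the 5-min minimum — with one protocol-specific amendment: when
REM latency from sleep onset is under 30 min, the NREM parts of the first
two detected cycles are combined into one (the first cycle's NREM part
would otherwise be unusably short for slow-wave-activity profiling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Hypnogram", "SleepCycle", "sleep_latency_10min", "segment_cycles",
           "sleep_efficiency", "STAGES"]

STAGES = ("W", "N1", "N2", "N3", "REM")
EPOCH_S = 30.0
SLAT_RUN_EPOCHS = 20              # 10 min of continuous sleep
NREM_MIN_EPOCHS = 30              # 15 min
REM_MIN_EPOCHS = 10               # 5 min
SHORT_REM_LATENCY_MIN = 30.0


@dataclass(frozen=True)
class Hypnogram:
    """Scored 30-s epochs from lights off to lights on."""

    stages: tuple
    lights_off_epoch: int = 0
    epoch_s: float = EPOCH_S

    def __post_init__(self):
        stages = tuple(self.stages)
        object.__setattr__(self, "stages", stages)
        if not stages:
            raise ValueError("hypnogram is empty")
        bad = set(stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages: {sorted(bad)}")
        if not (0 <= self.lights_off_epoch < len(stages)):
            raise ValueError("lights-off epoch outside the record")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def asleep(self) -> np.ndarray:
        """Boolean per epoch: any non-wake stage counts as sleep."""
        return np.array([s != "W" for s in self.stages])


@dataclass(frozen=True)
class SleepCycle:
    """One NREM–REM cycle; epoch intervals are half-open [start, end)."""

    nrem_intervals: tuple         # ((start, end), ...) possibly several when merged
    rem_interval: tuple | None    # (start, end), None for an open final cycle
    merged: bool = False
    open_cycle: bool = False

    @property
    def nrem_epochs(self) -> int:
        return sum(e - s for s, e in self.nrem_intervals)

    @property
    def rem_epochs(self) -> int:
        return 0 if self.rem_interval is None else (
            self.rem_interval[1] - self.rem_interval[0])


def sleep_latency_10min(hypnogram: Hypnogram,
                        run_epochs: int = SLAT_RUN_EPOCHS) -> float | None:
    """Minutes from lights off to the first epoch starting ≥ 10 min of
    continuous sleep; None when the record contains no such run."""
    asleep = hypnogram.asleep()[hypnogram.lights_off_epoch:]
    run = 0
    for i, s in enumerate(asleep):
        run = run + 1 if s else 0
        if run >= run_epochs:
            start = i - run_epochs + 1
            return start * hypnogram.epoch_s / 60.0
    return None


def _runs(labels, want) -> list[tuple[int, int]]:
    """Half-open index runs where label == want."""
    runs, start = [], None
    for i, lab in enumerate(labels):
        if lab == want and start is None:
            start = i
        elif lab != want and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(labels)))
    return runs


def segment_cycles(hypnogram: Hypnogram) -> list[SleepCycle]:
    """Split the night into NREM–REM cycles.

    Returns one :class:`SleepCycle` per completed cycle; a record without
    qualifying REM yields a single open cycle (``open_cycle=True``).
    """
    stages = hypnogram.stages
    asleep = hypnogram.asleep()
    if not asleep.any():
        raise ValueError("record contains no sleep")
    onset = int(np.argmax(asleep))

    rem_runs = _runs(stages, "REM")
    qualifying = [r for i, r in enumerate(rem_runs)
                  if i == 0 or (r[1] - r[0]) >= REM_MIN_EPOCHS]
    cycles: list[SleepCycle] = []
    nrem_start = onset
    for rem_start, rem_end in qualifying:
        if rem_start - nrem_start < NREM_MIN_EPOCHS:
            continue  # NREM episode too short: extend to the next REM episode
        cycles.append(SleepCycle(((nrem_start, rem_start),),
                                 (rem_start, rem_end)))
        nrem_start = rem_end
    if not cycles:
        return [SleepCycle(((onset, hypnogram.n_epochs),), None,
                           open_cycle=True)]

    first_rem_start = cycles[0].rem_interval[0]
    rem_latency_min = (first_rem_start - onset) * hypnogram.epoch_s / 60.0
    if rem_latency_min < SHORT_REM_LATENCY_MIN and len(cycles) >= 2:
        first, second = cycles[0], cycles[1]
        merged = SleepCycle(first.nrem_intervals + second.nrem_intervals,
                            second.rem_interval, merged=True)
        cycles = [merged] + cycles[2:]
    return cycles


def sleep_efficiency(hypnogram: Hypnogram,
                     lights_on_epoch: int | None = None) -> tuple[float, bool]:
    """(total sleep time / time in bed, screening flag for < 70 %)."""
    end = hypnogram.n_epochs if lights_on_epoch is None else lights_on_epoch
    start = hypnogram.lights_off_epoch
    if end <= start:
        raise ValueError("time in bed is zero")
    asleep = hypnogram.asleep()[start:end]
    seff = float(np.mean(asleep))
    return seff, seff < 0.70
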