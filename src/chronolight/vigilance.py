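"""Psychomotor vigilance (PVT) summaries and the visual-comfort score.

PVT trials with reaction times below 100 ms are anticipations and are
discarded; valid trials are summarised by the median RT and the means of the
fastest and slowest deciles (rank-based membership, ⌈n/10⌉ trials per
decile).  The visual-comfort score is the arithmetic mean of the four
comfort items (pleasantness, brightness, glare, colour temperature) on the
1–5 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PVTSession", "PVTSummary", "summarize_pvt", "visual_comfort_score"]

VALID_RT_MS = 100.0
MIN_TRIALS_FOR_DECILES = 10


@dataclass(frozen=True)
class PVTSession:
    """Raw trial list of one PVT administration."""

    participant: str
    condition: str
    evening: int
    time_min: float               # tick time relative to HBT
    reaction_times_ms: np.ndarray

    def __post_init__(self):
        rt = np.asarray(self.reaction_times_ms, dtype=float)
        object.__setattr__(self, "reaction_times_ms", rt)
        if rt.size and (not np.all(np.isfinite(rt)) or np.any(rt <= 0)):
            raise ValueError("reaction times must be finite and positive")


@dataclass(frozen=True)
class PVTSummary:
    n_valid: int
    median_ms: float
    fastest_decile_ms: float | None
    slowest_decile_ms: float | None

    def __post_init__(self):
        if self.fastest_decile_ms is not None:
            if not (self.fastest_decile_ms <= self.median_ms
                    <= self.slowest_decile_ms):
                raise ValueError("decile means must bracket the median")


def summarize_pvt(session: PVTSession,
                  valid_threshold_ms: float = VALID_RT_MS) -> PVTSummary:
    """Median and fastest/slowest-decile mean RT of valid trials.

    With fewer than 10 valid trials the decile means are undefined (None);
    with no valid trials the session cannot be summarised at all.
    """
    rt = session.reaction_times_ms
    valid = np.sort(rt[rt >= valid_threshold_ms])
    n = valid.size
    if n == 0:
        raise ValueError("no valid trials (all reaction times below "
                         f"{valid_threshold_ms:g} ms)")
    median = float(np.median(valid))
    if n < MIN_TRIALS_FOR_DECILES:
        return PVTSummary(n, median, None, None)
    k = math.ceil(n / 10)
    return PVTSummary(n, median,
                      fastest_decile_ms=float(valid[:k].mean()),
                      slowest_decile_ms=float(valid[-k:].mean()))


def visual_comfort_score(item_ratings, reverse_items=()) -> float:
    """Mean of the four visual-comfort items (1–5 scale).

    ``reverse_items`` lists 0-based item indices to reverse-code (6 − x)
    before averaging; by default raw values are averaged.
    """
    items = np.asarray(item_ratings, dtype=float)
    if items.shape != (4,):
        raise ValueError("expected exactly four comfort item ratings")
    if np.any(items < 1) or np.any(items > 5):
        raise ValueError("comfort ratings must be on the 1-5 scale")
    items = items.copy()
    for i in reverse_items:
        items[i] = 6.0 - items[i]
    return float(items.mean())
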