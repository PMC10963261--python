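"""Dim-light melatonin onset (DLMO) by hockey-stick fitting.

Evening salivary melatonin is flat (a + b·t) until secretion onset at t₀ and
rises parabolically afterwards:

    m(t) = a + b·t                      t <  t₀
    m(t) = a + b·t + c·(t − t₀)²        t ≥  t₀,   c ≥ 0

The switch point t₀ is the DLMO.  Fitting is least squares with t₀ found by
grid search on a 1-min grid; for each candidate switch the remaining
parameters solve a linear system.  The area-of-interest (AOI) threshold
(default 5 pg ml⁻¹) caps what may count as baseline: the switch cannot be
placed after the first sample exceeding the threshold, so supra-threshold
samples never enter the baseline segment.

A fit reports status ``no_rise`` when the fitted rise at the last sample is
within twice the baseline residual SD — profiles with no clear melatonin
increase, for which no DLMO is defined.

The estimator follows the model/results idiom: build a :class:`HockeyStick`
from data, call :meth:`~HockeyStick.fit`, inspect the returned
:class:`HockeyStickResults` (``summary()``, ``predict()``, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MelatoninProfile", "HockeyStick", "HockeyStickResults",
           "fit_hockeystick", "phase_shift", "suppression_series",
           "read_melatonin_csv"]

MIN_POINTS = 5
ASSAY_LOQ_PG_ML = 0.9  # assay limit of quantification; values are kept as reported


@dataclass(frozen=True)
class MelatoninProfile:
    """One participant-evening of timed melatonin concentrations."""

    participant: str
    condition: str
    evening: int
    times_min: np.ndarray         # minutes relative to HBT, strictly increasing
    concentrations: np.ndarray    # pg ml⁻¹, ≥ 0; NaN marks missing samples

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "concentrations", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be matching 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(c[np.isfinite(c)] < 0):
            raise ValueError("concentrations must be non-negative")

    def usable(self):
        keep = np.isfinite(self.concentrations)
        return self.times_min[keep], self.concentrations[keep]


class HockeyStick:
    """Piecewise linear–parabolic melatonin-onset model for one profile."""

    def __init__(self, times_min, concentrations, aoi_threshold: float = 5.0,
                 flat_baseline: bool = False, grid_step_min: float = 1.0):
        self.times = np.asarray(times_min, dtype=float)
        self.conc = np.asarray(concentrations, dtype=float)
        keep = np.isfinite(self.conc)
        self.times, self.conc = self.times[keep], self.conc[keep]
        if self.times.size < MIN_POINTS:
            raise ValueError(
                f"need at least {MIN_POINTS} usable samples, got {self.times.size}")
        self.aoi_threshold = float(aoi_threshold)
        self.flat_baseline = bool(flat_baseline)
        self.grid_step = float(grid_step_min)
        if np.all(self.conc > self.aoi_threshold):
            raise ValueError("all samples above the AOI threshold; no baseline")
        # Area of interest: the fit considers the onset region only — samples
        # up to and including the first two exceeding the threshold (two
        # supra-threshold anchors identify both the switch time and the rise
        # curvature).  Samples beyond that (full secretion, exposure-window
        # suppression) never influence the fit, and no supra-threshold sample
        # can fall in the baseline segment.
        above = np.flatnonzero(self.conc > self.aoi_threshold)
        if above.size:
            cut = above[min(2, above.size) - 1] + 1
            self.times, self.conc = self.times[:cut], self.conc[:cut]
            self._first_cross = self.times[above[0]]
        else:
            self._first_cross = self.times[-1]
        if self.times.size < MIN_POINTS:
            raise ValueError(
                f"fewer than {MIN_POINTS} samples inside the area of interest")

    @classmethod
    def from_profile(cls, profile: MelatoninProfile, **kwargs) -> "HockeyStick":
        return cls(profile.times_min, profile.concentrations, **kwargs)

    # -- fitting -----------------------------------------------------------

    def _candidate_grid(self) -> np.ndarray:
        t = self.times
        lo = t[1] + self.grid_step       # ≥ 2 baseline points before t₀
        hi = min(self._first_cross, t[-1] - self.grid_step)
        if hi < lo:
            hi = lo
        n = int(np.floor((hi - lo) / self.grid_step)) + 1
        return lo + self.grid_step * np.arange(n)

    def _solve_at(self, t0: float):
        """Least-squares (a, b, c≥0) and RSS for a fixed switch time."""
        t, y = self.times, self.conc
        rise = np.clip(t - t0, 0.0, None) ** 2
        cols = [np.ones_like(t), rise] if self.flat_baseline \
            else [np.ones_like(t), t, rise]
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        if beta[-1] < 0:  # c must be non-negative: refit the boundary model
            Xb = X[:, :-1]
            bb, *_ = np.linalg.lstsq(Xb, y, rcond=None)
            beta = np.append(bb, 0.0)
        resid = y - X @ beta
        if self.flat_baseline:
            a, b, c = beta[0], 0.0, beta[1]
        else:
            a, b, c = beta
        return float(a), float(b), float(c), float(resid @ resid)

    def fit(self) -> "HockeyStickResults":
        best = None
        for t0 in self._candidate_grid():
            a, b, c, rss = self._solve_at(t0)
            if best is None or rss < best[4] - 1e-12:
                best = (a, b, c, t0, rss)
        a, b, c, t0, rss = best

        baseline = self.times < t0
        base_resid = self.conc[baseline] - (a + b * self.times[baseline])
        base_sd = float(np.std(base_resid)) if baseline.sum() > 1 else 0.0
        rise_at_end = c * (self.times[-1] - t0) ** 2
        # absolute floor guards against numerically-zero rise coefficients
        floor = 1e-9 * max(1.0, float(np.max(self.conc)))
        status = "no_rise" if rise_at_end <= 2.0 * base_sd + floor else "ok"
        return HockeyStickResults(model=self, baseline_level=a, baseline_slope=b,
                                  rise_coefficient=c, dlmo_min=t0, rss=rss,
                                  status=status)


@dataclass(frozen=True)
class HockeyStickResults:
    """Fitted hockey-stick parameters; ``dlmo_min`` is the DLMO estimate."""

    model: HockeyStick
    baseline_level: float         # a, pg ml⁻¹
    baseline_slope: float         # b, pg ml⁻¹ min⁻¹
    rise_coefficient: float       # c, pg ml⁻¹ min⁻²
    dlmo_min: float               # t₀, minutes relative to HBT
    rss: float
    status: str                   # ok | no_rise

    def predict(self, times_min) -> np.ndarray:
        t = np.asarray(times_min, dtype=float)
        rise = np.clip(t - self.dlmo_min, 0.0, None) ** 2
        return (self.baseline_level + self.baseline_slope * t
                + self.rise_coefficient * rise)

    def as_dict(self) -> dict:
        return {"a": self.baseline_level, "b": self.baseline_slope,
                "c": self.rise_coefficient, "t0": self.dlmo_min,
                "rss": self.rss, "status": self.status}

    def summary(self) -> str:
        lines = [
            "Hockey-stick melatonin onset fit",
            "================================",
            f"status                    {self.status}",
            f"DLMO t0 (min rel. HBT)    {self.dlmo_min:10.1f}",
            f"baseline level a (pg/ml)  {self.baseline_level:10.3f}",
            f"baseline slope b          {self.baseline_slope:10.5f}",
            f"rise coefficient c        {self.rise_coefficient:10.6f}",
            f"residual sum of squares   {self.rss:10.4f}",
            f"n samples                 {self.model.times.size:10d}",
            f"AOI threshold (pg/ml)     {self.model.aoi_threshold:10.1f}",
        ]
        return "\n".join(lines)


def fit_hockeystick(profile: MelatoninProfile, aoi_threshold: float = 5.0,
                    **kwargs) -> HockeyStickResults:
    """Fit the hockey-stick model to a melatonin profile."""
    return HockeyStick.from_profile(profile, aoi_threshold=aoi_threshold,
                                    **kwargs).fit()


def phase_shift(fit_evening1: HockeyStickResults,
                fit_evening2: HockeyStickResults) -> float:
    """Circadian phase shift in minutes (positive = delay: later DLMO on
    evening 2).  Undefined when either fit found no melatonin rise."""
    for which, fit in (("evening 1", fit_evening1), ("evening 2", fit_evening2)):
        if fit.status != "ok":
            raise ValueError(f"DLMO undefined for {which}: status {fit.status!r}")
    return fit_evening2.dlmo_min - fit_evening1.dlmo_min


def suppression_series(profile: MelatoninProfile,
                       window_min=(30.0, 90.0)) -> pd.DataFrame:
    """Exposure-window melatonin samples for condition comparisons.

    Returns the samples with time in ``window_min`` (inclusive), flagging
    missing scheduled half-hour ticks; raises when the window is empty.
    """
    lo, hi = window_min
    inside = (profile.times_min >= lo) & (profile.times_min <= hi)
    t = profile.times_min[inside]
    c = profile.concentrations[inside]
    usable = np.isfinite(c)
    if not usable.any():
        raise ValueError("no melatonin samples inside the exposure window")
    expected = np.arange(lo, hi + 1e-9, 30.0)
    out = pd.DataFrame({
        "participant": profile.participant, "condition": profile.condition,
        "evening": profile.evening, "time_min_rel_hbt": t[usable],
        "concentration_pg_ml": c[usable],
    })
    out.attrs["missing_ticks"] = [float(e) for e in expected
                                  if not np.any(np.isclose(t[usable], e))]
    return out


def read_melatonin_csv(path) -> list[MelatoninProfile]:
    """Read a long-format melatonin table into per-evening profiles."""
    table = pd.read_csv(path)
    required = {"participant", "condition", "evening", "time_min_rel_hbt",
                "concentration_pg_ml"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"melatonin CSV missing columns: {sorted(missing)}")
    profiles = []
    for (pid, cond, ev), grp in table.groupby(
            ["participant", "condition", "evening"], sort=True):
        grp = grp.sort_values("time_min_rel_hbt")
        profiles.append(MelatoninProfile(
            str(pid), str(cond), int(ev),
            grp["time_min_rel_hbt"].to_numpy(dtype=float),
            grp["concentration_pg_ml"].to_numpy(dtype=float)))
    return profiles
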