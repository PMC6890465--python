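"""Behavioral phase quantification.

Eduction (the average-day activity profile obtained by folding multiday data
at the cycle length), smoothed peak-phase extraction, light-pulse phase
shifts, evening-peak phase relative to an internal control under temperature
cycles, and morning/evening anticipation scores.

Conventions
-----------
* Profiles are sampled at left-edge bin times ``i * bin_h`` within the cycle;
  ZT0 is lights-on (or, under a temperature cycle, the cryophase→thermophase
  transition), CT0 the projected lights-on of the last entrained day.
* Peak phase is the argmax of a centred circular moving average (default
  4 h); ties resolve to the earliest time in the search window.
* Phase shifts: positive = advance.  ``phase_shift`` returns
  ``peak(unpulsed) - peak(pulsed)``, so a light pulse that advances the clock
  yields a positive number.  ``relative_evening_phase`` returns
  ``peak(test) - peak(control)``, so an advanced knockdown is *negative*.
  Circular differences are mapped into ``(-cycle/2, +cycle/2]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import ActivityRecording, RunConfig

__all__ = [
    "EductionProfile",
    "PhaseEstimate",
    "AnticipationScore",
    "educe_profile",
    "smooth_profile",
    "peak_phase",
    "phase_shift",
    "relative_evening_phase",
    "anticipation_scores",
    "circular_difference",
]


@dataclass
class EductionProfile:
    """Average-day activity profile: per-bin mean over flies × days."""

    cycle_h: float
    bin_h: float
    mean: np.ndarray
    sem: np.ndarray
    n_flies: int
    days_included: tuple

    def __post_init__(self) -> None:
        n = int(round(self.cycle_h / self.bin_h))
        if self.mean.size != n:
            raise ValueError(
                f"profile has {self.mean.size} bins, cycle needs {n}"
            )
        if np.any(self.sem < 0):
            raise ValueError("SEM must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.mean.size) * self.bin_h


@dataclass
class PhaseEstimate:
    """Peak time (hours within the cycle) of a smoothed profile."""

    peak_time: float
    smoothing_h: float
    marker: str = "activity_peak"
    tie: bool = False
    undefined: bool = False


@dataclass
class AnticipationScore:
    """Percent of window activity occurring in the pre-transition hours."""

    morning: float
    evening: float
    windows: dict = field(default_factory=dict)
    undefined_morning: bool = False
    undefined_evening: bool = False


def _per_fly_profile(
    rec: ActivityRecording,
    phase_label: str | None,
    days,
    cycle_h: float,
    zt0_offset_h: float,
) -> np.ndarray:
    n_cols = int(round(cycle_h / rec.bin_h))
    if abs(n_cols * rec.bin_h - cycle_h) > 1e-9:
        raise ValueError("cycle length must be an integer number of bins")
    sel = np.ones(rec.n_bins, dtype=bool)
    if phase_label is not None and rec.protocol is not None:
        sel &= rec.protocol == phase_label
    if days is not None:
        pday = rec.phase_day()
        if pday is None:
            raise ValueError(f"{rec.fly_id}: day selection requires protocol labels")
        sel &= np.isin(pday, list(days))
    sel &= ~rec.missing
    if not sel.any():
        raise ValueError(f"{rec.fly_id}: empty day/phase selection")
    col = np.round((rec.time_h - zt0_offset_h) / rec.bin_h).astype(int) % n_cols
    sums = np.bincount(col[sel], weights=rec.counts[sel].astype(float), minlength=n_cols)
    n = np.bincount(col[sel], minlength=n_cols)
    prof = np.full(n_cols, np.nan)
    prof[n > 0] = sums[n > 0] / n[n > 0]
    return prof


def educe_profile(
    recordings: list[ActivityRecording],
    phase_label: str | None = "LD",
    days=None,
    cycle_h: float = 24.0,
    zt0_offset_h: float = 0.0,
) -> EductionProfile:
    """Fold selected days at ``cycle_h`` and average across flies and days.

    ``days`` selects 1-based day indices *within* the protocol phase (e.g.
    days 7–10 of a temperature cycle); ``None`` uses all days of the phase.
    All flies are included regardless of rhythmicity; missing bins are
    excluded from the averages.  SEM is over per-fly mean profiles.
    """
    if not recordings:
        raise ValueError("no recordings given")
    bins = {r.bin_length_min for r in recordings}
    if len(bins) != 1:
        raise ValueError("recordings must share a bin length")
    mats = np.vstack(
        [_per_fly_profile(r, phase_label, days, cycle_h, zt0_offset_h) for r in recordings]
    )
    mean = np.nanmean(mats, axis=0)
    n = mats.shape[0]
    if n > 1:
        sem = np.nanstd(mats, axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return EductionProfile(
        cycle_h=cycle_h,
        bin_h=recordings[0].bin_h,
        mean=mean,
        sem=sem,
        n_flies=n,
        days_included=tuple(days) if days is not None else (),
    )


def smooth_profile(values: np.ndarray, window_bins: int) -> np.ndarray:
    """Centred circular moving average; even windows are widened by one bin
    to stay centred.  Idempotent on constants and mass-preserving."""
    w = int(window_bins)
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return np.asarray(values, dtype=float)
    return ndimage.uniform_filter1d(np.asarray(values, dtype=float), size=w, mode="wrap")


def peak_phase(
    profile: EductionProfile,
    smoothing_h: float = 4.0,
    search_window: tuple[float, float] | None = None,
) -> PhaseEstimate:
    """Peak of the profile after a centred circular moving average.

    ``search_window=(a, b)`` restricts the argmax to cycle times in
    ``[a, b)`` (wrap-aware); ties resolve to the earliest time from ``a``.
    """
    if smoothing_h >= profile.cycle_h / 2:
        raise ValueError("smoothing window must be below half the cycle length")
    vals = np.where(np.isnan(profile.mean), np.nanmean(profile.mean), profile.mean)
    sm = smooth_profile(vals, int(round(smoothing_h / profile.bin_h)))
    if np.ptp(sm) <= 1e-12 * max(1.0, np.abs(sm).max()):
        return PhaseEstimate(float("nan"), smoothing_h, undefined=True)
    t = profile.times
    if search_window is None:
        a, b = 0.0, profile.cycle_h
    else:
        a, b = search_window
    a_m, b_m = a % profile.cycle_h, b % profile.cycle_h
    if a_m < b_m:
        inside = (t >= a_m) & (t < b_m)
    elif a_m == b_m:
        inside = np.ones_like(t, dtype=bool)
    else:
        inside = (t >= a_m) | (t < b_m)
    order = np.argsort((t - a_m) % profile.cycle_h)
    order = order[inside[order]]
    if order.size == 0:
        raise ValueError("search window contains no bins")
    best = sm[order].max()
    hits = order[sm[order] >= best - 1e-12 * max(1.0, abs(best))]
    return PhaseEstimate(
        peak_time=float(t[hits[0]]),
        smoothing_h=smoothing_h,
        tie=bool(hits.size > 1),
    )


def circular_difference(a: float, b: float, cycle_h: float = 24.0) -> float:
    """``a - b`` mapped into ``(-cycle/2, +cycle/2]``."""
    d = (a - b) % cycle_h
    if d > cycle_h / 2:
        d -= cycle_h
    return float(d)


def phase_shift(
    pulsed: list[ActivityRecording],
    unpulsed: list[ActivityRecording],
    phase_label: str | None = "DD",
    days=None,
    cycle_h: float = 24.0,
    smoothing_h: float = 4.0,
    zt0_offset_h: float = 0.0,
    search_window: tuple[float, float] | None = None,
) -> float:
    """Light-pulse phase shift from group-averaged smoothed profiles.

    Returns ``peak(unpulsed) - peak(pulsed)`` in hours: positive = advance,
    negative = delay.  Both groups must be analysed over the same post-pulse
    days in constant darkness.
    """
    shifts = []
    for group in (pulsed, unpulsed):
        prof = educe_profile(group, phase_label, days, cycle_h, zt0_offset_h)
        est = peak_phase(prof, smoothing_h, search_window)
        if est.undefined:
            raise ValueError("undefined peak phase in one group")
        shifts.append(est.peak_time)
    return circular_difference(shifts[1], shifts[0], cycle_h)


def relative_evening_phase(
    test: EductionProfile,
    internal_control: EductionProfile,
    smoothing_h: float = 4.0,
    search_window: tuple[float, float] = (6.0, 18.0),
) -> float:
    """Evening peak phase of a test genotype minus an internal control.

    Negative = advanced relative to the control.  The default search window
    (cycle hours 6–18, thermophase-referenced) brackets the evening peak and
    avoids locking onto transition startle.
    """
    if test.cycle_h != internal_control.cycle_h:
        raise ValueError("profiles must share a cycle length")
    a = peak_phase(test, smoothing_h, search_window)
    b = peak_phase(internal_control, smoothing_h, search_window)
    if a.undefined or b.undefined:
        raise ValueError("undefined evening peak")
    return circular_difference(a.peak_time, b.peak_time, test.cycle_h)


def _window_sum(profile: EductionProfile, lo: float, hi: float) -> float:
    lo = round(lo / profile.bin_h) * profile.bin_h
    hi = round(hi / profile.bin_h) * profile.bin_h
    t = profile.times
    idx = (t >= lo - 1e-9) & (t < hi - 1e-9)
    return float(np.nansum(profile.mean[idx]))


def anticipation_scores(
    profile: EductionProfile, config: RunConfig | None = None
) -> AnticipationScore:
    """Morning/evening anticipation phase scores of a ZT-indexed profile.

    Morning: percent of ZT17.5–23.5 activity falling in ZT20.5–23.5.
    Evening: percent of ZT5.5–11.5 activity falling in ZT8.5–11.5.
    An earlier (advanced) rise of activity *lowers* the score.  Window edges
    snap to the nearest bin edge.
    """
    config = config or RunConfig()
    win = {
        "morning_window": config.morning_window,
        "morning_late": config.morning_late,
        "evening_window": config.evening_window,
        "evening_late": config.evening_late,
    }
    out = {}
    flags = {}
    for side in ("morning", "evening"):
        total = _window_sum(profile, *win[f"{side}_window"])
        late = _window_sum(profile, *win[f"{side}_late"])
        if total <= 0:
            out[side], flags[side] = float("nan"), True
        else:
            out[side], flags[side] = 100.0 * late / total, False
            if not -1e-9 <= out[side] <= 100 + 1e-9:
                raise AssertionError("anticipation score outside [0, 100]")
    return AnticipationScore(
        morning=out["morning"],
        evening=out["evening"],
        windows=win,
        undefined_morning=flags["morning"],
        undefined_evening=flags["evening"],
    )
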