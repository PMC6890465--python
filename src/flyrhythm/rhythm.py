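"""Free-running period estimation and rhythmicity calling.

The statistic is the Sokolove–Bushell chi-squared periodogram.  For a trial
period of ``P`` analysis bins, all ``N`` available window bins are folded
into ``P`` circadian phase columns with means ``M_c`` over the ``n_c`` values
landing in column ``c``; with grand mean ``M`` over the same bins,

    Qp = N * sum_c n_c * (M_c - M)^2 / sum_i (x_i - M)^2.

This is the one-way fold-and-variance form whose null mean is ``P - 1``:
under the no-rhythm null Qp is approximately chi-squared with ``P - 1``
degrees of freedom, giving a per-period significance line at the ``1 - alpha``
quantile.  Every bin is used at every trial period (columns may hold ``K`` or
``K + 1`` values); truncating to complete cycles instead would hand trial
periods that divide the window length up to one extra cycle of data, biasing
the peak toward them by a full grid step.  The peak is the global maximum of ``Qp - sig_line`` over the trial
grid; *power* is that excess at the peak and *width* the extent (in hours) of
the contiguous grid span around the peak where Qp exceeds the line.  A fly is
called rhythmic when power > 20 and width > 1.5 h, both strict.

Missing bins are excluded from column means, the grand mean and the
denominator (never imputed); ``N`` in the formula is the count of bins
actually used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ActivityRecording, RunConfig

__all__ = [
    "PeriodogramResult",
    "chi_squared_periodogram",
    "call_rhythmicity",
    "summarize_genotypes",
]


@dataclass
class PeriodogramResult:
    """Qp spectrum over trial periods with its significance line and peak."""

    fly_id: str
    genotype: str
    trial_periods: np.ndarray
    qp: np.ndarray
    df: np.ndarray
    sig_line: np.ndarray
    peak_period: float
    power: float
    width: float
    rhythmic: bool
    undefined: bool
    n_bins_used: int
    bin_h: float

    def __post_init__(self) -> None:
        if not self.undefined:
            if not (np.isfinite(self.power) and np.isfinite(self.width)):
                raise ValueError("power/width must be finite when a peak exists")
            if np.any(self.qp < 0):
                raise ValueError("Qp must be non-negative")


def _select_window(rec: ActivityRecording, window: str | None) -> np.ndarray:
    if window is None or rec.protocol is None:
        return np.ones(rec.n_bins, dtype=bool)
    sel = rec.protocol == window
    if not sel.any():
        raise ValueError(f"{rec.fly_id}: no bins in protocol phase {window!r}")
    return sel


def _aggregate(
    counts: np.ndarray, missing: np.ndarray, bin_h: float, analysis_bin_h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sum raw bins into analysis bins; a group with any missing raw bin is
    missing.  Trailing bins that do not fill a group are dropped."""
    factor = analysis_bin_h / bin_h
    k = int(round(factor))
    if k < 1 or abs(factor - k) > 1e-9:
        raise ValueError(
            f"analysis bin {analysis_bin_h} h is not a multiple of the raw bin {bin_h} h"
        )
    if k == 1:
        return counts.astype(float), missing.copy()
    n = (counts.size // k) * k
    x = counts[:n].reshape(-1, k).sum(axis=1).astype(float)
    m = missing[:n].reshape(-1, k).any(axis=1)
    return x, m


def chi_squared_periodogram(
    recording: ActivityRecording,
    config: RunConfig | None = None,
    window: str | None = "DD",
) -> PeriodogramResult:
    """Chi-squared periodogram of one fly over a protocol window.

    ``window`` selects bins by protocol label (default the DD days; ``None``
    uses the whole recording).  Counts are first aggregated to
    ``config.analysis_bin_h`` (default 0.1 h) so that every trial period on
    the 0.1 h grid is an integer number of analysis bins.
    """
    config = config or RunConfig()
    sel = _select_window(recording, window)
    x, miss = _aggregate(
        recording.counts[sel], recording.missing[sel], recording.bin_h, config.analysis_bin_h
    )
    bin_h = config.analysis_bin_h
    periods = config.period_grid
    n_avail = x.size
    if n_avail * bin_h < 2 * config.period_max_h:
        raise ValueError(
            f"{recording.fly_id}: window holds {n_avail * bin_h:.1f} h, need at "
            f"least 2 cycles of the longest trial period ({2 * config.period_max_h:.1f} h)"
        )

    df = np.array([int(round(p / bin_h)) - 1 for p in periods], dtype=float)
    sig = stats.chi2.ppf(1.0 - config.alpha, df)

    valid = x[~miss]
    degenerate = valid.size == 0 or np.ptp(valid) == 0
    qp = np.zeros_like(periods)
    if not degenerate:
        for j, p in enumerate(periods):
            nbins = int(round(p / bin_h))
            if abs(nbins * bin_h - p) > 1e-9:
                raise ValueError(
                    f"trial period {p} h is not an integer number of {bin_h} h bins"
                )
            col = np.arange(n_avail) % nbins
            ok = ~miss
            col_n = np.bincount(col[ok], minlength=nbins)
            col_sum = np.bincount(col[ok], weights=x[ok], minlength=nbins)
            used = x[ok]
            if used.size == 0:
                continue
            grand = used.mean()
            denom = ((used - grand) ** 2).sum()
            if denom == 0:
                continue
            nz = col_n > 0
            cm = col_sum[nz] / col_n[nz]
            qp[j] = used.size * (col_n[nz] * (cm - grand) ** 2).sum() / denom

    if degenerate:
        return PeriodogramResult(
            fly_id=recording.fly_id,
            genotype=recording.genotype,
            trial_periods=periods,
            qp=qp,
            df=df,
            sig_line=sig,
            peak_period=float("nan"),
            power=float("nan"),
            width=float("nan"),
            rhythmic=False,
            undefined=True,
            n_bins_used=int((~miss).sum()),
            bin_h=bin_h,
        )

    excess = qp - sig
    i = int(np.argmax(excess))
    above = qp > sig
    width = 0.0
    if above[i]:
        lo = i
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = i
        while hi < above.size - 1 and above[hi + 1]:
            hi += 1
        width = (hi - lo + 1) * config.period_step_h
    result = PeriodogramResult(
        fly_id=recording.fly_id,
        genotype=recording.genotype,
        trial_periods=periods,
        qp=qp,
        df=df,
        sig_line=sig,
        peak_period=float(periods[i]),
        power=float(excess[i]),
        width=float(width),
        rhythmic=False,
        undefined=False,
        n_bins_used=int((~miss).sum()),
        bin_h=bin_h,
    )
    result.rhythmic = call_rhythmicity(result, config.power_min, config.width_min_h)
    return result


def call_rhythmicity(
    result: PeriodogramResult, power_min: float = 20.0, width_min: float = 1.5
) -> bool:
    """FaasX-style rhythmicity call: power > 20 and width > 1.5 h, strict."""
    if result.undefined:
        return False
    return bool(result.power > power_min and result.width > width_min)


def summarize_genotypes(results: list[PeriodogramResult]) -> pd.DataFrame:
    """Per-genotype summary: n, % rhythmic, period and power mean ± SEM.

    Period statistics are computed over rhythmic flies only, mirroring the
    usual screen-table column structure.
    """
    df = pd.DataFrame(
        {
            "genotype": [r.genotype for r in results],
            "rhythmic": [r.rhythmic for r in results],
            "period": [r.peak_period for r in results],
            "power": [r.power for r in results],
        }
    )
    rows = []
    for genotype, grp in df.groupby("genotype", sort=False):
        rh = grp[grp["rhythmic"]]
        rows.append(
            {
                "genotype": genotype,
                "n": len(grp),
                "pct_rhythmic": 100.0 * len(rh) / len(grp),
                "period_mean": rh["period"].mean() if len(rh) else float("nan"),
                "period_sem": rh["period"].sem() if len(rh) > 1 else float("nan"),
                "power_mean": rh["power"].mean() if len(rh) else float("nan"),
                "power_sem": rh["power"].sem() if len(rh) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
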