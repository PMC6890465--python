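"""RNAi-screen hit-calling with batch stratification.

Period screens carry strong batch structure: RNAi collections differ in
genetic background (TRiP control periods run ~0.3 h shorter than VDRC), the
GAL4 drivers add a dominant ~0.8 h lengthening, and VDRC KK lines with an
insertion at the 40D landing site gain a further non-specific lengthening.
Lines are therefore stratified by RNAi collection × driver — with the 40D KK
lines always their own stratum — and a line is a hit when its mean period
deviates from its stratum mean by more than two stratum standard deviations
(strict inequality), in either direction.

Tables use documented DataFrame schemas:

* screen records — ``line_id, gene, collection, driver, n_total, n_rhythmic,
  mean_period, sem, mean_power`` with ``collection`` in
  {TRiP, VDRC-GD, VDRC-KK, VDRC-KK-40D} and ``driver`` in {TD2, PD2, +};
* cutoffs — per ``stratum``: ``n_lines, mean, sd, low_cut, high_cut,
  defined``;
* hit calls — per line × driver: ``z``, ``direction`` in
  {long, short, none}, ``passes``, plus flags for lines that could not be
  classified (no stratum cutoffs) and for fully arrhythmic lines, which are
  reported as rhythmicity candidates, not period hits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "COLLECTION_GROUPS",
    "stratum_of",
    "compute_cutoffs",
    "call_hits",
    "period_histogram",
]

#: GD and non-40D KK VDRC lines pool into one VDRC stratum; 40D KK lines are
#: never pooled with the rest of the KK collection.
COLLECTION_GROUPS = {
    "TRiP": "TRiP",
    "VDRC-GD": "VDRC",
    "VDRC-KK": "VDRC",
    "VDRC-KK-40D": "40D-KK",
}

RECORD_COLUMNS = [
    "line_id",
    "gene",
    "collection",
    "driver",
    "n_total",
    "n_rhythmic",
    "mean_period",
    "sem",
    "mean_power",
]


def stratum_of(collection: str, driver: str) -> str:
    try:
        group = COLLECTION_GROUPS[collection]
    except KeyError:
        raise ValueError(
            f"unknown collection {collection!r}; expected one of {sorted(COLLECTION_GROUPS)}"
        ) from None
    return f"{group}x{driver}"


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("line_id", "collection", "driver", "mean_period") if c not in records]
    if missing:
        raise ValueError(f"screen records missing columns {missing}")
    df = records.copy()
    df["stratum"] = [stratum_of(c, d) for c, d in zip(df["collection"], df["driver"])]
    return df


def compute_cutoffs(records: pd.DataFrame, min_lines: int = 10) -> pd.DataFrame:
    """Per-stratum mean, SD and ±2 SD period cutoffs over line-level means.

    Lines whose flies were all arrhythmic (undefined mean period) do not
    enter the distributions.  Strata with fewer than ``min_lines`` defined
    lines get undefined cutoffs and a warning.
    """
    df = _check_records(records)
    rows = []
    for stratum, grp in df.groupby("stratum", sort=True):
        means = grp["mean_period"].dropna().to_numpy(dtype=float)
        n = means.size
        if n < max(min_lines, 2):
            warnings.warn(
                f"stratum {stratum}: only {n} lines with a defined period; "
                "cutoffs undefined",
                stacklevel=2,
            )
            rows.append(
                dict(stratum=stratum, n_lines=n, mean=np.nan, sd=np.nan,
                     low_cut=np.nan, high_cut=np.nan, defined=False)
            )
            continue
        mean = means.mean()
        sd = means.std(ddof=1)
        if sd == 0:
            warnings.warn(f"stratum {stratum}: degenerate zero SD", stacklevel=2)
        rows.append(
            dict(
                stratum=stratum,
                n_lines=n,
                mean=mean,
                sd=sd,
                low_cut=mean - 2 * sd,
                high_cut=mean + 2 * sd,
                defined=True,
            )
        )
    return pd.DataFrame(rows)


def call_hits(records: pd.DataFrame, cutoffs: pd.DataFrame) -> pd.DataFrame:
    """Classify each line against its stratum's 2-SD cutoffs (strict).

    A line passes when ``|mean_period - stratum mean| > 2 * stratum SD``; a
    line exactly at a cutoff does not pass.  Lines with no rhythmic flies are
    flagged ``rhythmicity_candidate`` and never period hits.
    """
    df = _check_records(records)
    cut = cutoffs.set_index("stratum")
    rows = []
    for rec in df.itertuples(index=False):
        row = dict(
            line_id=rec.line_id,
            driver=rec.driver,
            stratum=rec.stratum,
            stratum_mean=np.nan,
            stratum_sd=np.nan,
            z=np.nan,
            direction="none",
            passes=False,
            unclassified=False,
            rhythmicity_candidate=False,
        )
        if rec.stratum not in cut.index or not cut.loc[rec.stratum, "defined"]:
            row["unclassified"] = True
        elif pd.isna(rec.mean_period):
            row["rhythmicity_candidate"] = True
        else:
            mean = cut.loc[rec.stratum, "mean"]
            sd = cut.loc[rec.stratum, "sd"]
            diff = rec.mean_period - mean
            row["stratum_mean"] = mean
            row["stratum_sd"] = sd
            with np.errstate(divide="ignore", invalid="ignore"):
                row["z"] = diff / sd if sd > 0 else np.sign(diff) * np.inf
            if abs(diff) > 2 * sd:
                row["passes"] = True
                row["direction"] = "long" if diff > 0 else "short"
        rows.append(row)
    return pd.DataFrame(rows)


def period_histogram(records: pd.DataFrame, bin_h: float = 0.1) -> pd.DataFrame:
    """Histogram of line-level mean periods at 0.1 h bins, per stratum."""
    df = _check_records(records).dropna(subset=["mean_period"])
    rows = []
    for stratum, grp in df.groupby("stratum", sort=True):
        vals = grp["mean_period"].to_numpy(dtype=float)
        left = np.floor(vals / bin_h + 1e-9) * bin_h
        for edge, count in pd.Series(np.round(left, 10)).value_counts().sort_index().items():
            rows.append(dict(stratum=stratum, bin_left=edge, n_lines=int(count)))
    return pd.DataFrame(rows)
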