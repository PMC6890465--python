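"""Input/output formats, domain containers and run configuration.

Exactly two activity-input dialects are supported:

* **Trikinetics DAMSystem3 monitor text** — tab-delimited, 42 fields per row:
  reading index, date (``"8 Apr 14"``), time (``"09:36:00"``), monitor status
  (1 = OK), five unused fields, the on-board light sensor, then one beam-break
  count per channel for 32 channels.  Rows whose status is not OK contribute
  *missing* bins (masked, never zero-filled).
* **Tidy activity CSV** — one row per fly and bin with columns
  ``fly_id, genotype, bin_minutes, bin_index, count, light, temperature,
  phase, day, missing``.  ``phase`` is one of ``LD``/``DD``/``TC`` and ``day``
  the absolute (1-based) experiment day.

Any other layout is rejected with :class:`FormatError` naming the offending
line; files are never silently truncated.

Result collections are written as plain CSV in declared field order with
lossless float rendering, so every writer round-trips through ``pandas``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ActivityRecording",
    "RunConfig",
    "read_dam_file",
    "read_tidy_csv",
    "write_tidy_csv",
    "label_protocol",
    "write_results_table",
    "read_results_table",
]

PROTOCOL_LABELS = ("LD", "DD", "TC")

#: Field layout of one DAMSystem3 monitor row.
_DAM_FIELDS = 42
_DAM_CHANNELS = 32
_DAM_STATUS_OK = 1


class FormatError(ValueError):
    """An input file does not match its declared layout."""


@dataclass
class ActivityRecording:
    """One fly's binned beam-break counts plus environmental annotation.

    ``counts``, ``light``, ``missing`` and (when present) ``temperature``,
    ``protocol`` and ``day`` are per-bin arrays of equal length.  Times are
    measured in hours from the start of the recording; bin *i* covers
    ``[i, i+1) * bin_length_min / 60``.
    """

    fly_id: str
    genotype: str
    bin_length_min: float
    counts: np.ndarray
    light: np.ndarray
    temperature: np.ndarray | None = None
    protocol: np.ndarray | None = None  # per-bin label in {LD, DD, TC}
    day: np.ndarray | None = None  # absolute 1-based experiment day
    missing: np.ndarray | None = None
    start_time: datetime | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.light = np.asarray(self.light, dtype=bool)
        n = self.counts.size
        if self.missing is None:
            self.missing = np.zeros(n, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
        if self.protocol is not None:
            self.protocol = np.asarray(self.protocol, dtype=object)
        if self.day is not None:
            self.day = np.asarray(self.day, dtype=int)
        for name in ("light", "missing", "temperature", "protocol", "day"):
            arr = getattr(self, name)
            if arr is not None and arr.size != n:
                raise ValueError(
                    f"{self.fly_id}: {name} has {arr.size} bins, counts has {n}"
                )
        if np.any(self.counts < 0):
            raise ValueError(f"{self.fly_id}: negative counts")
        if self.bin_length_min <= 0 or abs(
            round(60 / self.bin_length_min) * self.bin_length_min - 60
        ) > 1e-9:
            raise ValueError(
                f"{self.fly_id}: bin length {self.bin_length_min} min must divide 60"
            )
        if self.protocol is not None:
            bad = set(np.unique(self.protocol)) - set(PROTOCOL_LABELS)
            if bad:
                raise ValueError(f"{self.fly_id}: unknown protocol labels {bad}")
        if self.day is not None and np.any(np.diff(self.day) < 0):
            raise ValueError(f"{self.fly_id}: day index decreases")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_h(self) -> float:
        return self.bin_length_min / 60.0

    @property
    def time_h(self) -> np.ndarray:
        """Left-edge bin times in hours from recording start."""
        return np.arange(self.n_bins) * self.bin_h

    def phase_day(self) -> np.ndarray | None:
        """Day index *within* each protocol phase (1-based), or None."""
        if self.protocol is None or self.day is None:
            return None
        out = np.zeros(self.n_bins, dtype=int)
        for label in PROTOCOL_LABELS:
            sel = self.protocol == label
            if not sel.any():
                continue
            first = self.day[sel].min()
            out[sel] = self.day[sel] - first + 1
        return out


def label_protocol(
    recording: ActivityRecording, phases: list[tuple[str, int]], cycle_h: float = 24.0
) -> ActivityRecording:
    """Annotate a recording in place with protocol phase labels and day index.

    ``phases`` is an ordered list of ``(label, n_days)`` such as
    ``[("LD", 3), ("DD", 5)]``; days are ``cycle_h`` hours long.
    """
    bins_per_day = int(round(cycle_h / recording.bin_h))
    labels = np.empty(recording.n_bins, dtype=object)
    days = np.zeros(recording.n_bins, dtype=int)
    pos, day0 = 0, 0
    for label, n_days in phases:
        if label not in PROTOCOL_LABELS:
            raise ValueError(f"unknown protocol label {label!r}")
        for d in range(n_days):
            lo, hi = pos, min(pos + bins_per_day, recording.n_bins)
            labels[lo:hi] = label
            days[lo:hi] = day0 + d + 1
            pos = hi
        day0 += n_days
    if pos < recording.n_bins:
        raise ValueError(
            f"protocol covers {pos} bins but recording has {recording.n_bins}"
        )
    recording.protocol = labels
    recording.day = days
    return recording


# ---------------------------------------------------------------------------
# DAMSystem3 monitor text


def read_dam_file(
    path: str | Path, bin_length_min: float = 1.0, genotype: str = ""
) -> list[ActivityRecording]:
    """Read a Trikinetics DAMSystem3 monitor file into 32 recordings.

    Bins from rows whose monitor status is not OK are flagged missing, not
    zero.  Timestamps must be strictly increasing and uniformly spaced at
    ``bin_length_min``.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != _DAM_FIELDS:
                raise FormatError(
                    f"{path.name}:{lineno}: expected {_DAM_FIELDS} tab-separated "
                    f"fields ({_DAM_CHANNELS} channels), got {len(parts)}"
                )
            try:
                stamp = datetime.strptime(
                    f"{parts[1]} {parts[2]}", "%d %b %y %H:%M:%S"
                )
                status = int(parts[3])
                light = int(parts[9]) > 0
                counts = [int(v) for v in parts[10:]]
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
            rows.append((lineno, stamp, status, light, counts))
    if not rows:
        raise FormatError(f"{path.name}: empty file")
    stamps = [r[1] for r in rows]
    step = timedelta(minutes=bin_length_min)
    for (_, a, *_rest), (ln_b, b, *_rest2) in zip(rows, rows[1:]):
        if b <= a:
            raise FormatError(f"{path.name}:{ln_b}: non-monotone timestamp {b}")
        if b - a != step:
            raise FormatError(
                f"{path.name}:{ln_b}: timestamp step {b - a} != {bin_length_min} min"
            )
    status_ok = np.array([r[2] == _DAM_STATUS_OK for r in rows])
    light = np.array([r[3] for r in rows], dtype=bool)
    matrix = np.array([r[4] for r in rows], dtype=int)  # (bins, channels)
    matrix[~status_ok, :] = 0
    out = []
    for ch in range(_DAM_CHANNELS):
        out.append(
            ActivityRecording(
                fly_id=f"{path.stem}:{ch + 1:02d}",
                genotype=genotype,
                bin_length_min=bin_length_min,
                counts=matrix[:, ch],
                light=light,
                missing=~status_ok,
                start_time=stamps[0],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tidy activity CSV

_TIDY_REQUIRED = ["fly_id", "genotype", "bin_minutes", "bin_index", "count", "light"]
_TIDY_OPTIONAL = ["temperature", "phase", "day", "missing"]


def write_tidy_csv(recordings: list[ActivityRecording], path: str | Path) -> None:
    """Write recordings in the tidy one-row-per-fly-bin CSV dialect."""
    frames = []
    for rec in recordings:
        df = pd.DataFrame(
            {
                "fly_id": rec.fly_id,
                "genotype": rec.genotype,
                "bin_minutes": rec.bin_length_min,
                "bin_index": np.arange(rec.n_bins),
                "count": rec.counts,
                "light": rec.light.astype(int),
                "missing": rec.missing.astype(int),
            }
        )
        if rec.temperature is not None:
            df["temperature"] = rec.temperature
        if rec.protocol is not None:
            df["phase"] = rec.protocol
        if rec.day is not None:
            df["day"] = rec.day
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tidy_csv(path: str | Path) -> list[ActivityRecording]:
    """Read the tidy activity CSV dialect back into recordings."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path.name}: empty file") from exc
    missing_cols = [c for c in _TIDY_REQUIRED if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path.name}: missing columns {missing_cols}")
    out = []
    for fly_id, grp in df.groupby("fly_id", sort=False):
        grp = grp.sort_values("bin_index")
        idx = grp["bin_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx.size)):
            raise FormatError(f"{path.name}: fly {fly_id}: bin_index not contiguous")
        bl = grp["bin_minutes"].unique()
        if bl.size != 1:
            raise FormatError(f"{path.name}: fly {fly_id}: bin_minutes not constant")
        out.append(
            ActivityRecording(
                fly_id=str(fly_id),
                genotype=str(grp["genotype"].iloc[0]),
                bin_length_min=float(bl[0]),
                counts=grp["count"].to_numpy(),
                light=grp["light"].to_numpy().astype(bool),
                temperature=grp["temperature"].to_numpy()
                if "temperature" in grp
                else None,
                protocol=grp["phase"].to_numpy() if "phase" in grp else None,
                day=grp["day"].to_numpy() if "day" in grp else None,
                missing=grp["missing"].to_numpy().astype(bool)
                if "missing" in grp
                else None,
            )
        )
    if not out:
        raise FormatError(f"{path.name}: no rows")
    return out


# ---------------------------------------------------------------------------
# Result tables


def write_results_table(records, path: str | Path, allow_empty: bool = False) -> None:
    """Write a result collection as CSV with a stable column order.

    ``records`` is a DataFrame or a sequence of dataclass instances; array
    fields (e.g. a periodogram's spectrum) are dropped, scalars kept in field
    order.  Floats use Python's shortest lossless representation, so the table
    round-trips exactly through :func:`read_results_table`.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        rows = []
        for item in records:
            d = dataclasses.asdict(item)
            rows.append(
                {
                    k: v
                    for k, v in d.items()
                    if v is None or np.isscalar(v) or isinstance(v, (bool, str))
                }
            )
        df = pd.DataFrame(rows)
    if df.empty and not allow_empty:
        raise ValueError("refusing to write an empty results table (allow_empty=False)")
    df.to_csv(path, index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Tunable analysis parameters with the defaults used throughout.

    Periodogram grid 18–30 h in 0.1 h steps on 0.1 h analysis bins, a 5%
    significance line, FaasX-style rhythmicity thresholds (power > 20,
    width > 1.5 h), a 4 h moving average for phase estimation, and the
    anticipation-score windows (morning: share of ZT17.5–23.5 activity inside
    ZT20.5–23.5; evening: share of ZT5.5–11.5 inside ZT8.5–11.5).
    """

    period_min_h: float = 18.0
    period_max_h: float = 30.0
    period_step_h: float = 0.1
    analysis_bin_h: float = 0.1
    alpha: float = 0.05
    power_min: float = 20.0
    width_min_h: float = 1.5
    smoothing_window_h: float = 4.0
    morning_window: tuple = (17.5, 23.5)
    morning_late: tuple = (20.5, 23.5)
    evening_window: tuple = (5.5, 11.5)
    evening_late: tuple = (8.5, 11.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_step_h <= 0:
            raise ValueError("period grid step must be positive")
        if not self.period_min_h < self.period_max_h:
            raise ValueError("period grid min must be below max")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("morning_window", "morning_late", "evening_window", "evening_late"):
            setattr(self, name, tuple(float(v) for v in getattr(self, name)))

    @property
    def period_grid(self) -> np.ndarray:
        n = int(round((self.period_max_h - self.period_min_h) / self.period_step_h))
        return np.round(self.period_min_h + np.arange(n + 1) * self.period_step_h, 10)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data = {k: list(v) if isinstance(v, tuple) else v for k, v in data.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
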