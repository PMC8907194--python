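"""Reading, writing and light/dark annotation of activity-monitor files.

Infrared activity monitors (Trikinetics DAM/LAM and compatible devices)
export tab-separated text files with exactly 42 columns and no header, one
row per sampling timestamp.  The dialect enforced here is the de-facto
DAMSystem3 layout:

==========  =======================================
column      meaning
==========  =======================================
1           record index (ignored on read)
2           date, ``D Mon YY`` (e.g. ``7 Mar 22``) or ISO ``YYYY-MM-DD``
3           time, ``HH:MM:SS``
4           monitor status (1 = valid reading)
5-9         reserved integers (written as 0, ignored on read)
10          light-sensor reading
11-42       beam-crossing counts for channels 1-32
==========  =======================================

Counts are non-negative integers; an empty or non-numeric channel cell is
loaded as an explicit missing value (NaN), never silently as zero, so that
validation can report it and imputation can repair it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MetadataError, MonitorFormatError, RangeError

N_CHANNELS = 32
N_COLUMNS = 42

_DATE_DIALECTS = ("%d %b %y", "%Y-%m-%d")
_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MonitorRecording:
    """One monitor file in memory: a regular time grid x 32 count channels.

    ``counts`` is a float matrix of shape (n_rows, 32); NaN marks a missing
    cell.  Timestamps label the *start* of each half-open sampling bin
    ``[t, t + sampling_interval)``.
    """

    source_name: str
    timestamps: pd.DatetimeIndex
    status: np.ndarray
    light_sensor: np.ndarray
    counts: np.ndarray
    sampling_interval: float  # seconds

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != N_CHANNELS:
            raise MonitorFormatError(
                f"counts must have {N_CHANNELS} channels, got shape {self.counts.shape}"
            )
        if len(self.timestamps) < 2:
            raise MonitorFormatError("a recording needs at least 2 rows")
        observed = self.counts[~np.isnan(self.counts)]
        if observed.size and (observed < 0).any():
            raise MonitorFormatError("negative counts are not allowed")

    @property
    def n_rows(self) -> int:
        return len(self.timestamps)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.counts).sum())

    def channel(self, channel_id: int) -> np.ndarray:
        """Counts of a 1-based channel."""
        if not 1 <= channel_id <= N_CHANNELS:
            raise ValueError(f"channel_id must be in 1..{N_CHANNELS}")
        return self.counts[:, channel_id - 1]

    def window(self, start: datetime, finish: datetime) -> "MonitorRecording":
        """Sub-recording covering ``[start, finish)`` (bin-start containment)."""
        mask = (self.timestamps >= start) & (self.timestamps < finish)
        if mask.sum() < 2:
            raise RangeError(
                f"window [{start}, {finish}) selects fewer than 2 rows of "
                f"{self.source_name}"
            )
        return MonitorRecording(
            source_name=self.source_name,
            timestamps=self.timestamps[mask],
            status=self.status[mask],
            light_sensor=self.light_sensor[mask],
            counts=self.counts[mask],
            sampling_interval=self.sampling_interval,
        )


@dataclass(frozen=True)
class LightCycleSpec:
    """A light-dark regime: cycle length, light hours, and clock time of ZT0.

    ``zt0_clock`` is the clock time of light onset (zeitgeber time zero).
    A standard zebrafish regime is ``LightCycleSpec(24, 14, time(9, 0))``
    i.e. 14L:10D with lights on at 09:00.
    """

    cycle_period_h: float
    light_hours: float
    zt0_clock: time

    def __post_init__(self) -> None:
        if self.cycle_period_h <= 0:
            raise ValueError("cycle_period_h must be > 0")
        if not 0 <= self.light_hours <= self.cycle_period_h:
            raise ValueError("light_hours must be within [0, cycle_period_h]")


@dataclass
class AnnotatedSeries:
    """A single channel's binned counts with zeitgeber-time annotation.

    ``zt`` is hours since the most recent light onset, in
    ``[0, cycle_period_h)``; ``phase`` is ``"light"`` where ``zt <
    light_hours`` else ``"dark"``; ``day_index`` counts elapsed full cycles
    from the first light onset at or before the window start.
    """

    channel_id: int
    bin_start: pd.DatetimeIndex
    counts: np.ndarray
    bin_seconds: float
    zt: np.ndarray
    phase: np.ndarray  # 'light' / 'dark'
    day_index: np.ndarray
    light_cycle: LightCycleSpec | None = None
    condition_label: str | None = None
    source_name: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def hours_from_start(self) -> np.ndarray:
        """Elapsed hours of each bin start since the first bin."""
        return (self.bin_start - self.bin_start[0]).total_seconds().to_numpy() / 3600.0

    @property
    def zeitgeber_hours(self) -> np.ndarray:
        """Continuous zeitgeber axis: day_index * cycle + zt."""
        period = self.light_cycle.cycle_period_h if self.light_cycle else 24.0
        return self.day_index * period + self.zt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_start,
                "counts": self.counts,
                "zt": self.zt,
                "phase": self.phase,
                "day_index": self.day_index,
            }
        )


@dataclass
class ConditionMetadata:
    """Channel-to-condition mapping across one or more monitor files.

    Backed by a table with the seven columns ``filename, start, finish,
    channels, label, order, zt0`` — one row per (file, condition) group.
    """

    rows: pd.DataFrame

    COLUMNS = ["filename", "start", "finish", "channels", "label", "order", "zt0"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.rows.columns]
        if missing:
            raise MetadataError(f"metadata table lacks columns: {missing}")
        self._check_unique_assignment()
        bad = self.rows[self.rows["start"] >= self.rows["finish"]]
        if len(bad):
            raise MetadataError("metadata rows with start >= finish")

    def _check_unique_assignment(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for _, row in self.rows.iterrows():
            for ch in row["channels"]:
                key = (row["filename"], ch)
                if key in seen and seen[key] != row["label"]:
                    raise MetadataError(
                        f"channel {ch} of {row['filename']} assigned to both "
                        f"{seen[key]!r} and {row['label']!r}"
                    )
                seen[key] = row["label"]

    # -- serialization (channels as comma-joined list, e.g. "1,2,5") --------

    def to_table(self) -> pd.DataFrame:
        out = self.rows.copy()
        out["channels"] = out["channels"].map(
            lambda chs: ",".join(str(c) for c in sorted(chs))
        )
        out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%d %H:%M:%S")
        out["finish"] = pd.to_datetime(out["finish"]).dt.strftime("%Y-%m-%d %H:%M:%S")
        out["zt0"] = out["zt0"].map(lambda t: t.strftime("%H:%M:%S"))
        return out[self.COLUMNS]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ConditionMetadata":
        rows = table.copy()
        rows["channels"] = rows["channels"].map(
            lambda s: sorted(int(c) for c in str(s).split(",") if str(c).strip())
        )
        rows["start"] = pd.to_datetime(rows["start"])
        rows["finish"] = pd.to_datetime(rows["finish"])
        rows["zt0"] = rows["zt0"].map(
            lambda s: s if isinstance(s, time) else datetime.strptime(str(s), "%H:%M:%S").time()
        )
        rows["order"] = rows["order"].astype(int)
        return cls(rows.reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConditionMetadata":
        return cls.from_table(pd.read_csv(path))


@dataclass
class ConditionDataset:
    """Annotated series grouped by condition label on a shared zeitgeber axis."""

    series: list[AnnotatedSeries]

    def by_condition(self) -> dict[str, list[AnnotatedSeries]]:
        out: dict[str, list[AnnotatedSeries]] = {}
        for s in self.series:
            out.setdefault(s.condition_label or "", []).append(s)
        return out

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.series:
            lab = s.condition_label or ""
            if lab not in seen:
                seen.append(lab)
        return seen


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _parse_date(text: str, line_no: int) -> datetime:
    for fmt in _DATE_DIALECTS:
        try:
            return datetime.strptime(text.strip(), fmt)
        except ValueError:
            continue
    raise MonitorFormatError(
        f"line {line_no}: cannot parse date {text!r} "
        f"(tried dialects {', '.join(_DATE_DIALECTS)})"
    )


def read_monitor_file(path: str | Path) -> MonitorRecording:
    """Parse a 42-column monitor file into a :class:`MonitorRecording`.

    Empty or non-numeric channel cells load as NaN (missing); validation and
    imputation deal with them downstream.  Raises
    :class:`~actimetry.errors.MonitorFormatError` on a wrong column count
    (naming the line), unparseable dates/times, or irregular timestamps.
    """
    path = Path(path)
    timestamps: list[datetime] = []
    status: list[int] = []
    light: list[int] = []
    counts: list[list[float]] = []

    with open(path, "r", newline="") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != N_COLUMNS:
                raise MonitorFormatError(
                    f"{path.name}, line {line_no}: expected {N_COLUMNS} "
                    f"tab-separated fields, found {len(fields)}"
                )
            day = _parse_date(fields[1], line_no)
            try:
                clock = datetime.strptime(fields[2].strip(), "%H:%M:%S").time()
            except ValueError as exc:
                raise MonitorFormatError(
                    f"{path.name}, line {line_no}: cannot parse time "
                    f"{fields[2]!r} (expected HH:MM:SS)"
                ) from exc
            timestamps.append(datetime.combine(day.date(), clock))
            status.append(_int_or_zero(fields[3]))
            light.append(_int_or_zero(fields[9]))
            row: list[float] = []
            for cell in fields[10:42]:
                cell = cell.strip()
                try:
                    row.append(float(int(cell)))
                except ValueError:
                    row.append(math.nan)
            counts.append(row)

    if len(timestamps) < 2:
        raise MonitorFormatError(f"{path.name}: fewer than 2 data rows")

    index = pd.DatetimeIndex(timestamps)
    deltas = np.diff(index.asi8) / 1e9
    if (deltas <= 0).any():
        raise MonitorFormatError(
            f"{path.name}: timestamps are not strictly increasing"
        )
    if not np.allclose(deltas, deltas[0]):
        raise MonitorFormatError(
            f"{path.name}: irregular sampling interval (saw "
            f"{sorted(set(deltas.round(3)))} s)"
        )

    return MonitorRecording(
        source_name=path.name,
        timestamps=index,
        status=np.asarray(status, dtype=int),
        light_sensor=np.asarray(light, dtype=int),
        counts=np.asarray(counts, dtype=float),
        sampling_interval=float(deltas[0]),
    )


def _int_or_zero(cell: str) -> int:
    try:
        return int(cell.strip())
    except ValueError:
        return 0


def _format_date(dt: datetime) -> str:
    return f"{dt.day} {_MONTH_ABBR[dt.month - 1]} {dt.year % 100:02d}"


def write_monitor_file(recording: MonitorRecording, path: str | Path) -> Path:
    """Serialize a complete recording back to the 42-column dialect.

    Refuses recordings with missing cells — impute first.  The output
    round-trips bit-exactly through :func:`read_monitor_file`.
    """
    if recording.n_missing:
        raise MonitorFormatError(
            f"recording has {recording.n_missing} missing cells; "
            "impute before writing (see actimetry.preprocess.impute_copy_mean)"
        )
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for i, ts in enumerate(recording.timestamps):
            fields = [
                str(i + 1),
                _format_date(ts),
                ts.strftime("%H:%M:%S"),
                str(int(recording.status[i])),
                "0", "0", "0", "0", "0",
                str(int(recording.light_sensor[i])),
            ]
            fields += [str(int(c)) for c in recording.counts[i]]
            fh.write("\t".join(fields) + "\n")
    return path


# ---------------------------------------------------------------------------
# zeitgeber annotation
# ---------------------------------------------------------------------------

def _first_onset_at_or_before(start: datetime, spec: LightCycleSpec) -> datetime:
    """Latest light onset <= start, on the lattice anchored at the clock
    occurrence of zt0 on the start's calendar day."""
    onset = datetime.combine(start.date(), spec.zt0_clock)
    period = timedelta(hours=spec.cycle_period_h)
    while onset > start:
        onset -= period
    while onset + period <= start:
        onset += period
    return onset


def annotate(
    recording: MonitorRecording,
    spec: LightCycleSpec,
    window: tuple[datetime, datetime] | None = None,
    channels: Sequence[int] | None = None,
    condition_label: str | None = None,
) -> list[AnnotatedSeries]:
    """Annotate every requested channel with zeitgeber time and phase.

    ``zt = ((t - anchor) mod cycle_period)`` in hours, where the anchor is
    the first light onset at or before the window start (day 0).
    """
    rec = recording if window is None else recording.window(*window)
    start = rec.timestamps[0].to_pydatetime()
    anchor = _first_onset_at_or_before(start, spec)

    elapsed_h = (rec.timestamps - anchor).total_seconds().to_numpy() / 3600.0
    zt = np.mod(elapsed_h, spec.cycle_period_h)
    day_index = np.floor(elapsed_h / spec.cycle_period_h).astype(int)
    phase = np.where(zt < spec.light_hours, "light", "dark")

    if channels is None:
        channels = range(1, N_CHANNELS + 1)
    out = []
    for ch in channels:
        out.append(
            AnnotatedSeries(
                channel_id=int(ch),
                bin_start=rec.timestamps,
                counts=rec.counts[:, int(ch) - 1].copy(),
                bin_seconds=rec.sampling_interval,
                zt=zt.copy(),
                phase=phase.copy(),
                day_index=day_index.copy(),
                light_cycle=spec,
                condition_label=condition_label,
                source_name=rec.source_name,
            )
        )
    return out


def assemble_conditions(
    metadata: ConditionMetadata,
    recordings: Iterable[MonitorRecording],
    cycle_period_h: float = 24.0,
    light_hours: float = 12.0,
) -> ConditionDataset:
    """Group channels from several files into labelled conditions.

    Each file is annotated with its *own* light-onset clock time (the
    metadata ``zt0`` column), so series recorded under shifted light
    schedules share a common zeitgeber axis.
    """
    by_name = {r.source_name: r for r in recordings}
    series: list[AnnotatedSeries] = []
    for _, row in metadata.rows.iterrows():
        rec = by_name.get(row["filename"])
        if rec is None:
            raise MetadataError(f"metadata references unknown file {row['filename']!r}")
        spec = LightCycleSpec(cycle_period_h, light_hours, row["zt0"])
        start = pd.Timestamp(row["start"]).to_pydatetime()
        finish = pd.Timestamp(row["finish"]).to_pydatetime()
        series.extend(
            annotate(
                rec,
                spec,
                window=(start, finish),
                channels=sorted(row["channels"]),
                condition_label=row["label"],
            )
        )
    return ConditionDataset(series=series)
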