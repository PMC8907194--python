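"""Scoring of movement stops, activity bouts and sleep from binned counts.

Small-organism sleep is operationalised as a prolonged quiescent state: a
run of consecutive zero-count bins at least as long as a species-specific
threshold (5 min is conventional for adult drosophila, 10 min for zebrafish
larvae).  Movement stops use the same zero-run machinery with their own
inactivity threshold; activity bouts are the maximal stretches between
consecutive stops that contain any activity.

Run-length comparison is inclusive (``>=`` threshold), so a threshold equal
to an observed run length detects the run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError
from .monitor_io import AnnotatedSeries

INTERVAL_COLUMNS = [
    "kind", "channel_id", "start", "end", "duration_min",
    "total_counts", "start_idx", "end_idx",
]


def _empty_intervals() -> pd.DataFrame:
    return pd.DataFrame(columns=INTERVAL_COLUMNS)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) bin-index ranges of the True runs."""
    padded = np.concatenate([[False], mask.astype(bool), [False]])
    edges = np.diff(padded.astype(int))
    return list(zip(np.nonzero(edges == 1)[0], np.nonzero(edges == -1)[0]))


def _intervals_from_runs(
    series: AnnotatedSeries, runs: list[tuple[int, int]], kind: str
) -> pd.DataFrame:
    bin_min = series.bin_seconds / 60.0
    step = pd.Timedelta(seconds=series.bin_seconds)
    rows = []
    for lo, hi in runs:
        rows.append(
            {
                "kind": kind,
                "channel_id": series.channel_id,
                "start": series.bin_start[lo],
                "end": series.bin_start[hi - 1] + step,
                "duration_min": (hi - lo) * bin_min,
                "total_counts": float(np.nansum(series.counts[lo:hi])),
                "start_idx": lo,
                "end_idx": hi,
            }
        )
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def detect_zero_runs(
    series: AnnotatedSeries, threshold_minutes: float, kind: str = "stop"
) -> pd.DataFrame:
    """Maximal zero-count runs lasting at least ``threshold_minutes``.

    ``kind`` is ``"stop"`` (movement stop, inactivity threshold) or
    ``"sleep_bout"`` (sleep threshold); the scoring rule is identical, only
    the threshold differs by convention.  Runs touching the series edges
    count.  Returns an interval table (one row per run).
    """
    if kind not in ("stop", "sleep_bout"):
        raise ParameterError(f"unknown interval kind {kind!r}")
    bin_min = series.bin_seconds / 60.0
    if threshold_minutes < bin_min:
        raise ParameterError(
            f"threshold {threshold_minutes} min is below the bin size {bin_min} min"
        )
    min_bins = int(np.ceil(threshold_minutes / bin_min - 1e-9))
    runs = [
        (lo, hi)
        for lo, hi in _bool_runs(series.counts == 0)
        if hi - lo >= min_bins
    ]
    return _intervals_from_runs(series, runs, kind)


def _group_ids(series: AnnotatedSeries, grouping) -> np.ndarray:
    """Per-bin group key array for the requested grouping.

    ``grouping`` is one of the named schemes or a custom per-bin key array
    of the same length as the series.
    """
    if not isinstance(grouping, str):
        keys = np.asarray(grouping, dtype=object)
        if len(keys) != len(series):
            raise ParameterError(
                f"custom grouping has {len(keys)} keys for {len(series)} bins"
            )
        return keys
    if grouping == "whole":
        return np.zeros(len(series), dtype=object)
    if grouping == "per_day":
        return series.day_index.astype(object)
    if grouping == "per_phase":
        return series.phase.astype(object)
    if grouping == "per_day_and_phase":
        return np.array(
            [(int(d), p) for d, p in zip(series.day_index, series.phase)],
            dtype=object,
        )
    raise ParameterError(f"unknown grouping {grouping!r}")


def activity_bouts(
    series: AnnotatedSeries,
    stops: pd.DataFrame,
    grouping: str = "whole",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Activity bouts between consecutive stops, with per-group summaries.

    A bout is a maximal interval between two consecutive stops (or between
    a series edge and the nearest stop) that contains at least one nonzero
    bin; sub-threshold zero runs at the edges of a bout belong to it.
    Returns ``(bout_table, summary)`` where the summary holds
    ``mean_bout_activity`` and ``mean_bout_duration_min`` per group (a bout
    is assigned to the group its start bin falls in); groups without bouts
    report NaN.
    """
    n = len(series)
    stop_mask = np.zeros(n, dtype=bool)
    for _, row in stops.iterrows():
        stop_mask[int(row["start_idx"]):int(row["end_idx"])] = True
    bout_runs = [
        (lo, hi)
        for lo, hi in _bool_runs(~stop_mask)
        if (series.counts[lo:hi] != 0).any()
    ]
    bouts = _intervals_from_runs(series, bout_runs, "activity_bout")

    gids = _group_ids(series, grouping)
    if len(bouts):
        bouts = bouts.assign(group=[gids[lo] for lo, _ in bout_runs])
        summary = (
            bouts.groupby("group", sort=True)
            .agg(
                n_bouts=("kind", "size"),
                mean_bout_activity=("total_counts", "mean"),
                mean_bout_duration_min=("duration_min", "mean"),
            )
            .reset_index()
        )
    else:
        bouts = bouts.assign(group=pd.Series(dtype=object))
        summary = pd.DataFrame(
            columns=["group", "n_bouts", "mean_bout_activity", "mean_bout_duration_min"]
        )
    return bouts, summary


def cumulative_activity(series: AnnotatedSeries) -> np.ndarray:
    """Running total of counts since the beginning of the analysis."""
    return np.cumsum(series.counts)


# ---------------------------------------------------------------------------
# sleep metrics
# ---------------------------------------------------------------------------

def sleep_mask(series: AnnotatedSeries, sleep_bouts: pd.DataFrame) -> np.ndarray:
    """Boolean per-bin mask of time covered by sleep bouts."""
    mask = np.zeros(len(series), dtype=bool)
    for _, row in sleep_bouts.iterrows():
        mask[int(row["start_idx"]):int(row["end_idx"])] = True
    return mask


def sleep_summary(
    series: AnnotatedSeries,
    sleep_bouts: pd.DataFrame,
    grouping: str = "per_day",
) -> pd.DataFrame:
    """Per-group sleep metrics from a scored sleep-bout table.

    One row per group with:

    - ``sleep_ratio``: fraction of the group's time covered by sleep bouts;
    - ``mean_sleep_bout_min``: mean duration of the sleep stretches inside
      the group (bouts are split at group boundaries, e.g. at light/dark
      transitions for phase groupings);
    - ``sleep_latency_min``: minutes from lights-off to the onset of the
      first sleep bout starting in that dark phase (mean over the group's
      dark phases that contain an onset; NaN when none does);
    - ``total_sleep_time_h``: hours asleep during the group's darkness;
    - ``waso_h``: dark hours awake after the first sleep onset of each dark
      phase (wake-after-sleep-onset).

    Phase-aware metrics need light/dark annotation on the series.
    """
    if grouping in ("per_phase", "per_day_and_phase") and series.light_cycle is None:
        raise ParameterError("phase grouping requires light/dark annotation")

    mask = sleep_mask(series, sleep_bouts)
    bin_min = series.bin_seconds / 60.0
    gids = _group_ids(series, grouping)
    onset_idx = set(int(i) for i in sleep_bouts["start_idx"]) if len(sleep_bouts) else set()
    dark = series.phase == "dark"

    rows = []
    for g in _unique_in_order(gids):
        in_g = np.array([x == g for x in gids])
        n_bins = int(in_g.sum())
        sub = mask & in_g
        sub_runs = _bool_runs(sub)
        # dark blocks inside the group: contiguous dark runs restricted to it
        dark_blocks = _bool_runs(dark & in_g)
        latencies, tst_bins, waso_bins = [], 0, 0
        for lo, hi in dark_blocks:
            tst_bins += int(mask[lo:hi].sum())
            onsets = sorted(i for i in onset_idx if lo <= i < hi)
            if onsets:
                latencies.append((onsets[0] - lo) * bin_min)
                waso_bins += int((~mask[onsets[0]:hi]).sum())
        rows.append(
            {
                "group": g,
                "n_bins": n_bins,
                "sleep_ratio": float(sub.sum()) / n_bins if n_bins else np.nan,
                "mean_sleep_bout_min": (
                    float(np.mean([(hi - lo) * bin_min for lo, hi in sub_runs]))
                    if sub_runs else np.nan
                ),
                "sleep_latency_min": float(np.mean(latencies)) if latencies else np.nan,
                "total_sleep_time_h": tst_bins * bin_min / 60.0,
                "waso_h": waso_bins * bin_min / 60.0,
            }
        )
    return pd.DataFrame(rows)


def _unique_in_order(values: np.ndarray) -> list:
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen
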