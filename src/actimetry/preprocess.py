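"""Validation, Copy Mean imputation, and re-binning of count series.

Missing channel cells (rare IR-sensor dropouts, or gaps in data converted
from other sources) are imputed with the Copy Mean method: the straight
line between a gap's flanking observations, corrected by how the
cross-channel mean trajectory deviates from its own straight line over the
same gap.  This preserves the shared within-gap shape of the cohort while
anchoring each channel at its own flanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ImputationError, ParameterError
from .monitor_io import AnnotatedSeries, MonitorRecording


@dataclass
class ValidationReport:
    """Outcome of format/integrity checks on one recording."""

    source_name: str
    column_count_ok: bool
    n_missing_cells: int
    missing_locations: list[tuple[int, int]] = field(default_factory=list)
    n_bad_status_rows: int = 0
    timestamp_regular: bool = True

    @property
    def ok(self) -> bool:
        return (
            self.column_count_ok
            and self.n_missing_cells == 0
            and self.timestamp_regular
        )

    def to_frame(self) -> pd.DataFrame:
        """Missing-cell listing, one row per (row, channel) pair."""
        return pd.DataFrame(
            self.missing_locations, columns=["row", "channel"], dtype=int
        )

    def summary(self) -> str:
        state = "OK" if self.ok else "ISSUES"
        return (
            f"{self.source_name}: {state} — {self.n_missing_cells} missing "
            f"cells, {self.n_bad_status_rows} rows with status != 1, "
            f"timestamps {'regular' if self.timestamp_regular else 'IRREGULAR'}"
        )


def validate(recording: MonitorRecording) -> ValidationReport:
    """Enumerate every missing cell and timestamp irregularity.

    Channels are reported 1-based, rows 0-based.  A report with
    ``ok == True`` certifies the recording analysis-ready.
    """
    rows, cols = np.nonzero(np.isnan(recording.counts))
    locations = [(int(r), int(c) + 1) for r, c in zip(rows, cols)]
    deltas = np.diff(recording.timestamps.asi8) / 1e9
    regular = bool((deltas > 0).all() and np.allclose(deltas, deltas[0]))
    return ValidationReport(
        source_name=recording.source_name,
        column_count_ok=recording.counts.shape[1] == 32,
        n_missing_cells=len(locations),
        missing_locations=locations,
        n_bad_status_rows=int((recording.status != 1).sum()),
        timestamp_regular=regular,
    )


# ---------------------------------------------------------------------------
# Copy Mean imputation
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def impute_copy_mean(recording: MonitorRecording) -> MonitorRecording:
    """Fill every missing cell with the Copy Mean estimate.

    Interior gap in channel c between observed flanks at rows a < b::

        imputed(t) = LI_c(t) + (M(t) - LI_M(t))

    where ``LI_c`` is the line through the channel's flanking values,
    ``M(t)`` the mean over channels observed at t, and ``LI_M`` the line
    through ``M(a)`` and ``M(b)``.  Edge gaps use the flat extension
    ``v_edge + (M(t) - M(t_edge))``.  Results are rounded half-away-from-zero
    and clipped at 0 (monitor files carry integer counts).  Observed cells
    are untouched; the output has no missing cells.
    """
    counts = recording.counts
    missing = np.isnan(counts)
    if not missing.any():
        return recording

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
        mean_traj = np.nanmean(counts, axis=1)

    filled = counts.copy()
    n = counts.shape[0]
    for ch in np.nonzero(missing.any(axis=0))[0]:
        col = counts[:, ch]
        obs = np.nonzero(~np.isnan(col))[0]
        if obs.size == 0:
            raise ImputationError(
                f"channel {ch + 1} of {recording.source_name} has no observed values"
            )
        gaps = _missing_runs(np.isnan(col))
        for lo, hi in gaps:  # half-open [lo, hi)
            t = np.arange(lo, hi)
            if np.isnan(mean_traj[t]).any():
                raise ImputationError(
                    f"all channels missing at row(s) "
                    f"{t[np.isnan(mean_traj[t])].tolist()}; no mean trajectory"
                )
            a, b = lo - 1, hi  # flanking observed rows, if inside the grid
            if a >= 0 and b < n:
                frac = (t - a) / (b - a)
                li_c = col[a] + frac * (col[b] - col[a])
                li_m = mean_traj[a] + frac * (mean_traj[b] - mean_traj[a])
                est = li_c + (mean_traj[t] - li_m)
            elif a >= 0:  # trailing edge gap
                est = col[a] + (mean_traj[t] - mean_traj[a])
            else:  # leading edge gap
                est = col[b] + (mean_traj[t] - mean_traj[b])
            filled[t, ch] = np.clip(_round_half_away(est), 0, None)

    return MonitorRecording(
        source_name=recording.source_name,
        timestamps=recording.timestamps,
        status=recording.status,
        light_sensor=recording.light_sensor,
        counts=filled,
        sampling_interval=recording.sampling_interval,
    )


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of the True runs of a 1-D mask."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0]
    return list(zip(starts, stops))


# ---------------------------------------------------------------------------
# re-binning
# ---------------------------------------------------------------------------

def bin_counts(series: AnnotatedSeries, bin_minutes: float) -> AnnotatedSeries:
    """Sum counts into larger half-open bins of ``bin_minutes``.

    The new bin size must be an integer multiple of the current one; a
    trailing partial window is dropped (with a warning).  Total counts are
    conserved over the fully covered span.
    """
    target_s = bin_minutes * 60.0
    ratio = target_s / series.bin_seconds
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ParameterError(
            f"bin size {bin_minutes} min is not an integer multiple of the "
            f"sampling interval {series.bin_seconds} s"
        )
    if k == 1:
        return series
    n_out = len(series) // k
    dropped = len(series) - n_out * k
    if dropped:
        warnings.warn(
            f"bin_counts: dropping {dropped} trailing sample(s) not filling "
            f"a {bin_minutes}-min bin",
            stacklevel=2,
        )
    take = n_out * k
    sel = slice(0, take, k)  # first input bin of each window labels the output
    return AnnotatedSeries(
        channel_id=series.channel_id,
        bin_start=series.bin_start[sel],
        counts=series.counts[:take].reshape(n_out, k).sum(axis=1),
        bin_seconds=target_s,
        zt=series.zt[sel],
        phase=series.phase[sel],
        day_index=series.day_index[sel],
        light_cycle=series.light_cycle,
        condition_label=series.condition_label,
        source_name=series.source_name,
    )
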