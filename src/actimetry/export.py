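"""Structured result export and plot-ready matrices.

Results go out as XLSX workbooks (with CSV mirrors) in the two orientations
mainstream statistics packages expect: conditions in columns (wide) or
conditions in rows (long).  Every workbook carries a settings sheet echoing
the analysis parameters verbatim, and a descriptive-statistics sheet
(n, mean, SEM, SD, median, Q1, Q3 per condition).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .monitor_io import AnnotatedSeries


@dataclass
class AnalysisSettings:
    """Every tunable of an analysis run; echoed into each export."""

    activity_bin_min: float = 10.0
    sleep_bin_min: float = 1.0
    inactivity_threshold_min: float = 5.0
    sleep_threshold_min: float = 10.0
    death_threshold_h: float = 24.0
    cycle_period_h: float = 24.0
    light_hours: float = 14.0
    zt0_clock: str = "09:00:00"
    period_lo_h: float = 16.0
    period_hi_h: float = 32.0
    chi_square_step_h: float = 0.25
    ls_n_periods: int = 512
    alpha: float = 0.05
    dfa_n_scales: int = 20
    death_policy: str = "trim_after_death"
    orientation: str = "conditions_in_columns"
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"setting": [f.name for f in fields(self)],
             "value": [getattr(self, f.name) for f in fields(self)]}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnalysisSettings":
        kwargs = {}
        lookup = dict(zip(frame["setting"], frame["value"]))
        for f in fields(cls):
            if f.name in lookup:
                kwargs[f.name] = _cast(lookup[f.name], f.default)
        return cls(**kwargs)


def _cast(value, default):
    if isinstance(default, bool):
        return str(value).lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(float(value))
    if isinstance(default, float):
        return float(value)
    return str(value)


def descriptive_stats(values) -> dict:
    """n, mean, SEM, SD (sample), median, Q1, Q3 of a value collection."""
    a = np.asarray(values, dtype=float)
    a = a[~np.isnan(a)]
    n = len(a)
    sd = float(a.std(ddof=1)) if n > 1 else float("nan")
    return {
        "n": n,
        "mean": float(a.mean()) if n else float("nan"),
        "sem": sd / np.sqrt(n) if n > 1 else float("nan"),
        "sd": sd,
        "median": float(np.median(a)) if n else float("nan"),
        "q1": float(np.percentile(a, 25)) if n else float("nan"),
        "q3": float(np.percentile(a, 75)) if n else float("nan"),
    }


def export_results(
    results: pd.DataFrame, orientation: str = "conditions_in_columns"
) -> pd.DataFrame:
    """Reshape a long result table into the requested orientation.

    ``results`` must be long form with a ``condition`` column, a ``value``
    column, and any identifying columns (channel, group...).  Long
    orientation returns it unchanged; wide pivots to one column per
    condition, identified rows.
    """
    if orientation == "conditions_in_rows":
        return results.reset_index(drop=True)
    if orientation != "conditions_in_columns":
        raise ValueError(f"unknown orientation {orientation!r}")
    ids = [c for c in results.columns if c not in ("condition", "value")]
    if not ids:
        results = results.assign(_row=results.groupby("condition").cumcount())
        ids = ["_row"]
    wide = results.pivot_table(
        index=ids, columns="condition", values="value", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    return wide


def stats_by_condition(results: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics of the value column per condition."""
    rows = []
    for label, sub in results.groupby("condition", sort=True):
        rows.append({"condition": label, **descriptive_stats(sub["value"])})
    return pd.DataFrame(rows)


def write_workbook(
    path: str | Path,
    data: dict[str, pd.DataFrame],
    settings: AnalysisSettings,
    csv_mirror: bool = True,
) -> Path:
    """Write data sheets + stats-per-sheet + settings sheet; CSV mirrors too."""
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for name, frame in data.items():
            frame.to_excel(xl, sheet_name=name[:31], index=False)
            if "condition" in frame.columns and "value" in frame.columns:
                stats_by_condition(frame).to_excel(
                    xl, sheet_name=f"{name[:25]}_stats", index=False
                )
        settings.to_frame().to_excel(xl, sheet_name="settings", index=False)
    if csv_mirror:
        stem = path.with_suffix("")
        for name, frame in data.items():
            frame.to_csv(f"{stem}_{name}.csv", index=False)
        settings.to_frame().to_csv(f"{stem}_settings.csv", index=False)
    return path


def read_settings_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_excel(path, sheet_name="settings")


# ---------------------------------------------------------------------------
# actogram / chronogram matrices
# ---------------------------------------------------------------------------

def actogram_matrix(series: AnnotatedSeries, mode: str = "single") -> np.ndarray:
    """Day-by-bin activity matrix for actogram rendering.

    Single mode: row r holds cycle r's bins, columns indexed by zeitgeber
    time.  Double (staggered) mode: row r is the concatenation of cycles r
    and r + 1, so each row's second half equals the next row's first half;
    the last row is right-padded with NaN.  Bins absent from the series
    (e.g. trimmed after death) stay NaN.
    """
    if series.light_cycle is None:
        raise ValueError("actogram needs a light-cycle annotation")
    period_h = series.light_cycle.cycle_period_h
    p_bins = int(round(period_h * 3600.0 / series.bin_seconds))
    n_days = int(series.day_index.max()) + 1
    mat = np.full((n_days, p_bins), np.nan)
    cols = np.round(series.zt * 3600.0 / series.bin_seconds).astype(int) % p_bins
    mat[series.day_index, cols] = series.counts
    if mode == "single":
        return mat
    if mode != "double":
        raise ValueError(f"unknown actogram mode {mode!r}")
    out = np.full((n_days, 2 * p_bins), np.nan)
    out[:, :p_bins] = mat
    out[:-1, p_bins:] = mat[1:]
    return out


def average_cycle_profile(series: AnnotatedSeries) -> pd.DataFrame:
    """Mean counts per zeitgeber bin over all cycles (average LD-cycle chronogram)."""
    mat = actogram_matrix(series, mode="single")
    bin_h = series.bin_seconds / 3600.0
    return pd.DataFrame(
        {
            "zt_h": np.arange(mat.shape[1]) * bin_h,
            "mean_counts": np.nanmean(mat, axis=0),
        }
    )
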