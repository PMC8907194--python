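"""Backward death detection and Kaplan-Meier survival analysis.

An animal that dies shows zero counts from its death until the end of the
experiment, so death is detected *backwards* from the last timepoint: if the
terminal run of zero-count bins lasts at least the user-defined death
threshold, the channel is scored dead and the time of death is the last bin
with nonzero activity; otherwise the channel is censored at the window end.
Dead channels can then be dropped entirely, truncated at death (keeping the
pre-death behaviour available for time-dependent analyses), or kept as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from datetime import datetime

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import ParameterError
from .monitor_io import AnnotatedSeries, ConditionDataset


@dataclass(frozen=True)
class SurvivalRecord:
    """Outcome of death detection for one channel."""

    channel_id: int
    condition_label: str | None
    status: str  # 'dead' | 'censored'
    event_time_h: float  # hours from analysis start
    time_of_death_clock: datetime | None = None
    source_name: str | None = None

    @property
    def dead(self) -> bool:
        return self.status == "dead"


def detect_death(
    series: AnnotatedSeries, death_threshold_hours: float
) -> SurvivalRecord:
    """Score one channel dead or censored from its terminal inactivity run.

    Dead iff the terminal zero-count run lasts >= ``death_threshold_hours``
    (inclusive); the time of death is the start of the last nonzero bin.  An
    all-zero channel is scored dead at the window start (and flagged with a
    warning: it usually indicates an empty channel or sensor fault).
    """
    bin_h = series.bin_seconds / 3600.0
    if death_threshold_hours < bin_h:
        raise ParameterError("death threshold is below the bin size")
    counts = series.counts
    nz = np.nonzero(counts != 0)[0]
    span_h = len(counts) * bin_h
    if nz.size == 0:
        warnings.warn(
            f"channel {series.channel_id}: no activity at all — scored dead at "
            "window start (empty channel?)",
            stacklevel=2,
        )
        return SurvivalRecord(
            channel_id=series.channel_id,
            condition_label=series.condition_label,
            status="dead",
            event_time_h=0.0,
            time_of_death_clock=series.bin_start[0].to_pydatetime(),
            source_name=series.source_name,
        )
    last_nz = int(nz[-1])
    terminal_zero_h = (len(counts) - 1 - last_nz) * bin_h
    if terminal_zero_h >= death_threshold_hours:
        return SurvivalRecord(
            channel_id=series.channel_id,
            condition_label=series.condition_label,
            status="dead",
            event_time_h=last_nz * bin_h,
            time_of_death_clock=series.bin_start[last_nz].to_pydatetime(),
            source_name=series.source_name,
        )
    return SurvivalRecord(
        channel_id=series.channel_id,
        condition_label=series.condition_label,
        status="censored",
        event_time_h=span_h,
        time_of_death_clock=None,
        source_name=series.source_name,
    )


def detect_deaths(
    dataset: ConditionDataset, death_threshold_hours: float
) -> list[SurvivalRecord]:
    """Death detection over every channel of a dataset."""
    return [detect_death(s, death_threshold_hours) for s in dataset.series]


def apply_death_policy(
    dataset: ConditionDataset,
    records: list[SurvivalRecord],
    policy: str = "trim_after_death",
) -> ConditionDataset:
    """Apply a death-handling policy before downstream analyses.

    - ``drop_animal``: remove dead channels entirely;
    - ``trim_after_death``: truncate each dead channel just after its time of
      death, preserving pre-death behaviour;
    - ``keep_all``: identity.
    """
    if policy not in ("drop_animal", "trim_after_death", "keep_all"):
        raise ParameterError(f"unknown death policy {policy!r}")
    if policy == "keep_all":
        return dataset
    by_key = {
        (r.source_name, r.channel_id, r.condition_label): r for r in records
    }
    out = []
    for s in dataset.series:
        rec = by_key.get((s.source_name, s.channel_id, s.condition_label))
        if rec is None or not rec.dead:
            out.append(s)
            continue
        if policy == "drop_animal":
            continue
        # trim: keep bins up to and including the last nonzero bin
        keep = int(round(rec.event_time_h * 3600.0 / s.bin_seconds)) + 1
        keep = max(keep, 1)
        out.append(
            AnnotatedSeries(
                channel_id=s.channel_id,
                bin_start=s.bin_start[:keep],
                counts=s.counts[:keep].copy(),
                bin_seconds=s.bin_seconds,
                zt=s.zt[:keep],
                phase=s.phase[:keep],
                day_index=s.day_index[:keep],
                light_cycle=s.light_cycle,
                condition_label=s.condition_label,
                source_name=s.source_name,
            )
        )
    return ConditionDataset(series=out)


def records_table(records: list[SurvivalRecord]) -> pd.DataFrame:
    """One row per channel: status and time of death / last-activity timepoint."""
    return pd.DataFrame(
        {
            "source": [r.source_name for r in records],
            "channel_id": [r.channel_id for r in records],
            "condition": [r.condition_label for r in records],
            "status": [r.status for r in records],
            "event_time_h": [r.event_time_h for r in records],
            "time_of_death": [r.time_of_death_clock for r in records],
        }
    )


def kaplan_meier(
    records: list[SurvivalRecord], by_condition: bool = True
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves, one per condition label (or pooled).

    At each distinct death time t_j with d_j deaths among n_j at risk the
    curve multiplies by (1 - d_j/n_j); censored records leave the curve flat
    but shrink the risk set.  Returns, per curve, a step-function frame with
    ``time_h``, ``survival`` and ``n_at_risk``; S(0) = 1 and S is
    nonincreasing.
    """
    if not records:
        raise ParameterError("no survival records")
    groups: dict[str, list[SurvivalRecord]] = {}
    if by_condition:
        for r in records:
            groups.setdefault(r.condition_label or "", []).append(r)
    else:
        groups["all"] = list(records)

    out: dict[str, pd.DataFrame] = {}
    for label, recs in groups.items():
        times = np.array([r.event_time_h for r in recs], dtype=float)
        events = np.array([r.dead for r in recs], dtype=bool)
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=events)
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
        out[label] = pd.DataFrame(
            {
                "time_h": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                "n_at_risk": at_risk.to_numpy(dtype=float),
            }
        )
    return out
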