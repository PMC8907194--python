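"""Ground-truthed synthetic monitor recordings.

Generates multi-channel count series emulating what infrared activity
monitors record: baseline locomotion with programmable periodic rhythms
(circadian ~24 h, circatidal ~12.4 h, or arbitrary), Poisson count noise,
sleep bouts (runs of zeros), deaths (terminal zeros), transient stimulus
responses (exponentially decaying rate bursts, e.g. the startle peak after
a sudden light-to-dark transition), and planted missing cells.  Every
generated recording comes with its ground truth, so recovery can be tested
end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .monitor_io import (
    N_CHANNELS,
    LightCycleSpec,
    MonitorRecording,
    _format_date,
)


@dataclass(frozen=True)
class RhythmComponent:
    """One additive periodic rate component (counts/bin at the peak)."""

    period_h: float
    amplitude: float
    phase_h: float = 0.0  # time of peak (sinusoid) / onset (square)
    waveform: str = "sinusoid"  # 'sinusoid' | 'square'
    duty: float = 0.5  # fraction of the cycle a square wave is on

    def rate(self, t_h: np.ndarray) -> np.ndarray:
        if self.waveform == "sinusoid":
            return self.amplitude * np.cos(2 * np.pi * (t_h - self.phase_h) / self.period_h)
        if self.waveform == "square":
            frac = np.mod(t_h - self.phase_h, self.period_h) / self.period_h
            return np.where(frac < self.duty, self.amplitude, 0.0)
        raise ParameterError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class TransientEvent:
    """Exponentially decaying rate increment starting at ``time_h``."""

    time_h: float
    added_rate: float
    decay_h: float

    def rate(self, t_h: np.ndarray) -> np.ndarray:
        dt = t_h - self.time_h
        return np.where(dt >= 0, self.added_rate * np.exp(-dt / self.decay_h), 0.0)


@dataclass
class SyntheticSpec:
    """Full description of a synthetic recording; the seed fixes the output."""

    n_channels: int = 8
    days: float = 3.0
    sampling_interval_s: float = 60.0
    baseline_rate: float = 2.0  # counts per bin
    components: list[RhythmComponent] = field(default_factory=list)
    noise: str = "poisson"  # 'poisson' | 'none'
    sleep_bouts: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    death_times_h: dict[int, float] = field(default_factory=dict)
    missing_cells: int | list[tuple[int, int]] = 0
    transients: list[TransientEvent] = field(default_factory=list)
    start: datetime = datetime(2022, 3, 7, 9, 0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_channels <= N_CHANNELS:
            raise ParameterError(f"n_channels must be in 1..{N_CHANNELS}")
        if self.noise not in ("poisson", "none"):
            raise ParameterError(f"unknown noise model {self.noise!r}")
        for ch, bouts in self.sleep_bouts.items():
            death = self.death_times_h.get(ch)
            if death is not None:
                for start_h, dur_h in bouts:
                    if start_h >= death:
                        raise ParameterError(
                            f"channel {ch}: sleep bout at {start_h} h starts "
                            f"after death at {death} h"
                        )


def generate_recording(spec: SyntheticSpec) -> tuple[MonitorRecording, dict]:
    """Draw one recording and return it with its ground truth.

    Ground-truth keys: ``periods_h`` (true component periods),
    ``sleep_bouts`` / ``death_times_h`` (as specified), ``missing_cells``
    (list of (row, 1-based channel)), ``deleted_values`` (the counts blanked
    out), and ``rates`` (the composed noise-free rate matrix).
    """
    rng = np.random.default_rng(spec.seed)
    n_rows = int(round(spec.days * 24 * 3600 / spec.sampling_interval_s))
    if n_rows < 2:
        raise ParameterError("spec spans fewer than 2 samples")
    bin_h = spec.sampling_interval_s / 3600.0
    t_h = np.arange(n_rows) * bin_h

    rate = np.full(n_rows, float(spec.baseline_rate))
    for comp in spec.components:
        rate = rate + comp.rate(t_h)
    for ev in spec.transients:
        rate = rate + ev.rate(t_h)
    rate = np.clip(rate, 0.0, None)
    rates = np.tile(rate[:, None], (1, spec.n_channels))

    if spec.noise == "poisson":
        counts = rng.poisson(rates).astype(float)
    else:
        counts = np.round(rates)

    for ch, bouts in spec.sleep_bouts.items():
        for start_h, dur_h in bouts:
            lo = int(round(start_h / bin_h))
            hi = int(round((start_h + dur_h) / bin_h))
            counts[lo:hi, ch - 1] = 0.0
    for ch, death_h in spec.death_times_h.items():
        lo = int(round(death_h / bin_h))
        counts[lo:, ch - 1] = 0.0
        if lo > 0:
            counts[lo - 1, ch - 1] = max(counts[lo - 1, ch - 1], 1.0)  # pin last activity

    # pad unused channels with independent baseline noise so the file is full
    full = np.zeros((n_rows, N_CHANNELS))
    full[:, : spec.n_channels] = counts
    if spec.n_channels < N_CHANNELS:
        pad = N_CHANNELS - spec.n_channels
        if spec.noise == "poisson":
            full[:, spec.n_channels:] = rng.poisson(
                spec.baseline_rate, size=(n_rows, pad)
            )
        else:
            full[:, spec.n_channels:] = round(spec.baseline_rate)

    if isinstance(spec.missing_cells, int):
        k = spec.missing_cells
        cells = []
        if k:
            rows = rng.choice(n_rows, size=k, replace=True)
            chans = rng.integers(1, spec.n_channels + 1, size=k)
            cells = sorted(set(zip(rows.tolist(), chans.tolist())))
    else:
        cells = [(int(r), int(c)) for r, c in spec.missing_cells]
    deleted = [float(full[r, c - 1]) for r, c in cells]
    for r, c in cells:
        full[r, c - 1] = np.nan

    timestamps = pd.date_range(
        spec.start, periods=n_rows, freq=pd.Timedelta(seconds=spec.sampling_interval_s)
    )
    recording = MonitorRecording(
        source_name=f"synthetic_seed{spec.seed}.txt",
        timestamps=pd.DatetimeIndex(timestamps),
        status=np.ones(n_rows, dtype=int),
        light_sensor=np.zeros(n_rows, dtype=int),
        counts=full,
        sampling_interval=float(spec.sampling_interval_s),
    )
    truth = {
        "periods_h": [c.period_h for c in spec.components],
        "phases_h": [c.phase_h for c in spec.components],
        "sleep_bouts": dict(spec.sleep_bouts),
        "death_times_h": dict(spec.death_times_h),
        "missing_cells": cells,
        "deleted_values": deleted,
        "rates": rates,
    }
    return recording, truth


def write_raw_monitor_file(recording: MonitorRecording, path: str | Path) -> Path:
    """Serialize a recording allowing missing cells (written as empty fields).

    Test-data emission path only: the analysis writer
    (:func:`actimetry.monitor_io.write_monitor_file`) refuses missing data.
    """
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for i, ts in enumerate(recording.timestamps):
            cells = [
                "" if np.isnan(c) else str(int(c)) for c in recording.counts[i]
            ]
            fields = [
                str(i + 1), _format_date(ts), ts.strftime("%H:%M:%S"),
                str(int(recording.status[i])), "0", "0", "0", "0", "0",
                str(int(recording.light_sensor[i])),
            ] + cells
            fh.write("\t".join(fields) + "\n")
    return path


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

ZEBRAFISH_LD = LightCycleSpec(24.0, 14.0, datetime(2022, 1, 1, 9, 0).time())


def make_fixture_suite(seed: int = 0) -> dict[str, dict]:
    """Deterministic named fixtures exercising every analysis path.

    Returns ``{name: {"spec", "recording", "truth", "light_cycle"}}`` with:

    - ``circadian``: 14L:10D-entrained 24 h sinusoidal rhythm, 1-min bins,
      plus planted sleep bouts on channel 1;
    - ``circatidal``: ~12.4 h sub-daily rhythm (intertidal species class);
    - ``arrhythmic``: flat Poisson noise;
    - ``dying_cohort``: staggered deaths for survival analysis;
    - ``gappy``: planted missing cells for validation/imputation;
    - ``transient``: decaying activity burst after a light-to-dark switch.
    """
    suite: dict[str, dict] = {}

    def add(name: str, spec: SyntheticSpec, light=ZEBRAFISH_LD) -> None:
        rec, truth = generate_recording(spec)
        suite[name] = {
            "spec": spec, "recording": rec, "truth": truth, "light_cycle": light,
        }

    add(
        "circadian",
        SyntheticSpec(
            n_channels=8, days=6, sampling_interval_s=60, baseline_rate=6.0,
            components=[RhythmComponent(24.0, 4.0, phase_h=6.0)],
            sleep_bouts={1: [(14.5, 0.5), (38.25, 0.75)]},
            seed=seed,
        ),
    )
    add(
        "circatidal",
        SyntheticSpec(
            n_channels=4, days=8, sampling_interval_s=600, baseline_rate=40.0,
            components=[RhythmComponent(12.4, 30.0, phase_h=3.0)],
            seed=seed + 1,
        ),
    )
    add(
        "arrhythmic",
        SyntheticSpec(
            n_channels=4, days=4, sampling_interval_s=60, baseline_rate=2.0,
            seed=seed + 2,
        ),
    )
    add(
        "dying_cohort",
        SyntheticSpec(
            n_channels=8, days=5, sampling_interval_s=600, baseline_rate=5.0,
            death_times_h={1: 48.0, 2: 72.0, 3: 96.0},
            seed=seed + 3,
        ),
    )
    add(
        "gappy",
        SyntheticSpec(
            n_channels=4, days=2, sampling_interval_s=60, baseline_rate=3.0,
            missing_cells=5, seed=seed + 4,
        ),
    )
    add(
        "transient",
        SyntheticSpec(
            n_channels=2, days=1, sampling_interval_s=60, baseline_rate=1.0,
            transients=[TransientEvent(time_h=14.0, added_rate=25.0, decay_h=0.25)],
            seed=seed + 5,
        ),
    )
    return suite
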