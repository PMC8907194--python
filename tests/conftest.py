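import numpy as np
import pytest

from actimetry import synthetic


@pytest.fixture(scope="session")
def fixture_suite():
    """Deterministic synthetic recordings with ground truth (seed 0)."""
    return synthetic.make_fixture_suite(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_toy_recording(counts, start="2022-03-07 09:00:00", interval_s=60.0):
    """Small in-memory recording from an (n, <=32) count array (NaN = missing)."""
    import pandas as pd

    from actimetry.monitor_io import N_CHANNELS, MonitorRecording

    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    full = np.ones((n, N_CHANNELS))
    full[:, : counts.shape[1]] = counts
    ts = pd.date_range(start, periods=n, freq=pd.Timedelta(seconds=interval_s))
    return MonitorRecording(
        source_name="toy.txt",
        timestamps=pd.DatetimeIndex(ts),
        status=np.ones(n, dtype=int),
        light_sensor=np.zeros(n, dtype=int),
        counts=full,
        sampling_interval=interval_s,
    )


def make_series(counts, bin_seconds=600.0, light_hours=14.0, cycle_h=24.0,
                start_zt=0.0):
    """Annotated single-channel series directly from a count vector."""
    import pandas as pd

    from actimetry.monitor_io import AnnotatedSeries, LightCycleSpec
    from datetime import time

    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    bin_h = bin_seconds / 3600.0
    zt = np.mod(start_zt + np.arange(n) * bin_h, cycle_h)
    day = ((start_zt + np.arange(n) * bin_h) // cycle_h).astype(int)
    ts = pd.date_range("2022-03-07 09:00:00", periods=n,
                       freq=pd.Timedelta(seconds=bin_seconds))
    return AnnotatedSeries(
        channel_id=1,
        bin_start=pd.DatetimeIndex(ts),
        counts=counts,
        bin_seconds=bin_seconds,
        zt=zt,
        phase=np.where(zt < light_hours, "light", "dark"),
        day_index=day,
        light_cycle=LightCycleSpec(cycle_h, light_hours, time(9, 0)),
    )
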