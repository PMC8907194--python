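"""Monitor-file parsing, serialization and zeitgeber annotation."""

from datetime import datetime, time

import numpy as np
import pandas as pd
import pytest

from actimetry import monitor_io, synthetic
from actimetry.errors import MetadataError, MonitorFormatError, RangeError
from actimetry.monitor_io import (
    ConditionMetadata,
    LightCycleSpec,
    annotate,
    assemble_conditions,
    read_monitor_file,
    write_monitor_file,
)

from conftest import make_toy_recording


def _write_lines(path, rows):
    path.write_text("\n".join("\t".join(r) for r in rows) + "\n")


def _toy_lines(n=3, count="1", interval_min=1):
    rows = []
    for i in range(n):
        fields = [str(i + 1), "7 Mar 22", f"09:{i * interval_min:02d}:00",
                  "1", "0", "0", "0", "0", "0", "0"] + [count] * 32
        rows.append(fields)
    return rows


class TestRead:
    def test_identity_parse(self, tmp_path):
        p = tmp_path / "toy.txt"
        _write_lines(p, _toy_lines())
        rec = read_monitor_file(p)
        assert rec.counts.shape == (3, 32)
        assert (rec.counts == 1).all()
        assert rec.sampling_interval == 60.0

    def test_wrong_column_count_names_line(self, tmp_path):
        rows = _toy_lines()
        rows[1] = rows[1][:-1]  # 41 fields
        p = tmp_path / "bad.txt"
        _write_lines(p, rows)
        with pytest.raises(MonitorFormatError, match="line 2"):
            read_monitor_file(p)

    def test_empty_cell_loads_as_missing(self, tmp_path):
        rows = _toy_lines()
        rows[1][15] = ""  # channel 6 of row 2
        p = tmp_path / "gap.txt"
        _write_lines(p, rows)
        rec = read_monitor_file(p)
        assert rec.n_missing == 1
        assert np.isnan(rec.counts[1, 5])

    def test_non_numeric_cell_is_missing_not_zero(self, tmp_path):
        rows = _toy_lines()
        rows[0][12] = "xx"
        p = tmp_path / "gap.txt"
        _write_lines(p, rows)
        assert read_monitor_file(p).n_missing == 1

    def test_irregular_timestamps_rejected(self, tmp_path):
        rows = _toy_lines(4)
        rows[2][2] = "09:02:30"  # increasing but unevenly spaced
        p = tmp_path / "irr.txt"
        _write_lines(p, rows)
        with pytest.raises(MonitorFormatError, match="irregular"):
            read_monitor_file(p)

    def test_non_monotonic_timestamps_rejected(self, tmp_path):
        rows = _toy_lines(4)
        rows[2][2] = "09:05:00"
        p = tmp_path / "dec.txt"
        _write_lines(p, rows)
        with pytest.raises(MonitorFormatError, match="increasing"):
            read_monitor_file(p)

    def test_bad_date_reports_dialects(self, tmp_path):
        rows = _toy_lines()
        rows[0][1] = "Mar 7 2022"
        p = tmp_path / "bad.txt"
        _write_lines(p, rows)
        with pytest.raises(MonitorFormatError, match="%d %b %y"):
            read_monitor_file(p)

    def test_iso_dates_accepted(self, tmp_path):
        rows = _toy_lines()
        for r in rows:
            r[1] = "2022-03-07"
        p = tmp_path / "iso.txt"
        _write_lines(p, rows)
        assert read_monitor_file(p).timestamps[0] == pd.Timestamp("2022-03-07 09:00:00")


class TestWrite:
    def test_round_trip_bit_exact(self, tmp_path, fixture_suite):
        rec = fixture_suite["circatidal"]["recording"]
        p = write_monitor_file(rec, tmp_path / "out.txt")
        back = read_monitor_file(p)
        assert np.array_equal(rec.counts, back.counts)
        assert (rec.timestamps == back.timestamps).all()
        assert np.array_equal(rec.status, back.status)

    def test_refuses_missing_cells(self, tmp_path, fixture_suite):
        rec = fixture_suite["gappy"]["recording"]
        with pytest.raises(MonitorFormatError, match="imput"):
            write_monitor_file(rec, tmp_path / "out.txt")

    def test_every_line_has_42_fields(self, tmp_path, fixture_suite):
        rec = fixture_suite["transient"]["recording"]
        p = write_monitor_file(rec, tmp_path / "out.txt")
        for line in p.read_text().splitlines():
            assert len(line.split("\t")) == 42


class TestAnnotate:
    LD = LightCycleSpec(24.0, 14.0, time(9, 0))

    def _rec(self, hours=48, start="2022-03-07 09:00:00"):
        return make_toy_recording(np.ones((hours * 60, 1)), start=start)

    def test_zt13_is_light(self):
        # lights on 09:00, 14L:10D -> 22:00 same day is ZT13, light phase
        s = annotate(self._rec(), self.LD, channels=[1])[0]
        i = 13 * 60
        assert s.zt[i] == pytest.approx(13.0)
        assert s.phase[i] == "light"

    def test_zt14_5_is_dark(self):
        s = annotate(self._rec(), self.LD, channels=[1])[0]
        i = int(14.5 * 60)
        assert s.zt[i] == pytest.approx(14.5)
        assert s.phase[i] == "dark"

    def test_half_hour_stimulus_cycle(self):
        # 0.5L:0.5D hourly cycle: 20 min after onset is light
        spec = LightCycleSpec(1.0, 0.5, time(9, 0))
        s = annotate(self._rec(hours=4), spec, channels=[1])[0]
        assert s.phase[20] == "light"
        assert s.phase[40] == "dark"

    def test_day_zero_anchored_before_window(self):
        # start at 15:00: most recent onset was 09:00 -> zt starts at 6
        s = annotate(self._rec(start="2022-03-07 15:00:00"), self.LD, channels=[1])[0]
        assert s.zt[0] == pytest.approx(6.0)
        assert s.day_index[0] == 0

    def test_periodicity_under_cycle_shift(self):
        r1 = self._rec()
        r2 = self._rec(start="2022-03-09 09:00:00")  # +2 cycles
        s1 = annotate(r1, self.LD, channels=[1])[0]
        s2 = annotate(r2, self.LD, channels=[1])[0]
        assert np.allclose(s1.zt, s2.zt)
        assert (s1.phase == s2.phase).all()

    def test_window_outside_recording(self):
        with pytest.raises(RangeError):
            annotate(self._rec(), self.LD,
                     window=(datetime(2023, 1, 1), datetime(2023, 1, 2)))


class TestConditions:
    def _metadata(self):
        rows = pd.DataFrame(
            {
                "filename": ["a.txt", "b.txt"],
                "start": [pd.Timestamp("2022-03-07 09:00"),
                          pd.Timestamp("2022-03-07 21:00")],
                "finish": [pd.Timestamp("2022-03-08 09:00"),
                           pd.Timestamp("2022-03-08 21:00")],
                "channels": [[1], [1]],
                "label": ["ctrl", "ctrl"],
                "order": [1, 1],
                "zt0": [time(9, 0), time(21, 0)],
            }
        )
        return ConditionMetadata(rows)

    def test_alignment_on_shared_zeitgeber_axis(self):
        ra = make_toy_recording(np.ones((24 * 60, 1)), start="2022-03-07 09:00:00")
        ra.source_name = "a.txt"
        rb = make_toy_recording(np.ones((24 * 60, 1)), start="2022-03-07 21:00:00")
        rb.source_name = "b.txt"
        ds = assemble_conditions(self._metadata(), [ra, rb], light_hours=14.0)
        for s in ds.series:
            assert s.zt[0] == pytest.approx(0.0)  # both start at their own ZT0

    def test_duplicate_channel_assignment_rejected(self):
        rows = self._metadata().rows.copy()
        rows.loc[1, "filename"] = "a.txt"
        rows.loc[1, "label"] = "treated"
        with pytest.raises(MetadataError, match="channel 1"):
            ConditionMetadata(rows)

    def test_metadata_csv_round_trip(self, tmp_path):
        md = self._metadata()
        p = tmp_path / "meta.csv"
        md.to_csv(p)
        back = ConditionMetadata.read_csv(p)
        pd.testing.assert_frame_equal(back.to_table(), md.to_table())

    def test_missing_file_lookup_error(self):
        ra = make_toy_recording(np.ones((24 * 60, 1)))
        ra.source_name = "a.txt"
        with pytest.raises(MetadataError, match="b.txt"):
            assemble_conditions(self._metadata(), [ra])
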