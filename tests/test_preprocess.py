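"""Device-export parsing, binning, sleep consolidation, day segmentation."""

import logging

import numpy as np
import pandas as pd
import pytest

from heartphase import preprocess as pre


def T(s):
    return pd.Timestamp(s)


def make_records(hr=None, steps=None, sleeps=()):
    hr = hr if hr is not None else pd.Series(dtype=float)
    steps = steps if steps is not None else pd.Series(dtype=float)
    return pre.RawRecordSet(hr=hr, steps=steps, sleep_intervals=list(sleeps))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

class TestReaders:
    def test_generic_three_rows(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "timestamp,stream,value\n"
            "2024-01-01 00:00,hr,70\n"
            "2024-01-01 00:05,hr,72\n"
            "2024-01-01 00:10,steps,30\n"
        )
        rec = pre.read_device_export([p], "generic")
        assert len(rec.hr) == 2 and len(rec.steps) == 1
        assert rec.sleep_intervals == []

    def test_generic_sleep_pairing(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "timestamp,stream,value\n"
            "2024-01-01 23:00,sleep_start,0\n"
            "2024-01-02 07:00,sleep_end,0\n"
        )
        rec = pre.read_device_export([p], "generic")
        assert rec.sleep_intervals == [(T("2024-01-01 23:00"), T("2024-01-02 07:00"))]

    def test_fitbit_split_empty_sleep_file(self, tmp_path):
        (tmp_path / "HR.csv").write_text("timestamp,bpm\n2024-01-01 00:00,70\n")
        (tmp_path / "Step.csv").write_text("timestamp,steps\n2024-01-01 00:00,12\n")
        (tmp_path / "Sleep_Stage.csv").write_text("start,end,stage\n")
        rec = pre.read_device_export(sorted(tmp_path.glob("*.csv")), "fitbit_split")
        assert len(rec.hr) == 1 and len(rec.steps) == 1
        assert rec.sleep_intervals == []

    def test_fitbit_wake_stage_not_sleep(self, tmp_path):
        (tmp_path / "Sleep_Stage.csv").write_text(
            "start,end,stage\n"
            "2024-01-01 23:00,2024-01-02 01:00,light\n"
            "2024-01-02 01:00,2024-01-02 01:30,wake\n"
            "2024-01-02 01:30,2024-01-02 07:00,deep\n"
        )
        rec = pre.read_device_export([tmp_path / "Sleep_Stage.csv"], "fitbit_split")
        assert len(rec.sleep_intervals) == 2

    def test_malformed_row_skipped_and_logged(self, tmp_path, caplog):
        rows = ["timestamp,stream,value"]
        rows += [f"2024-01-01 {h:02d}:00,hr,70" for h in range(10)]
        rows[5] = "not-a-time,hr,70"
        p = tmp_path / "d.csv"
        p.write_text("\n".join(rows) + "\n")
        with caplog.at_level(logging.WARNING, logger="heartphase.preprocess"):
            rec = pre.read_device_export([p], "generic")
        assert len(rec.hr) == 9
        assert any("skipped 1 malformed" in m for m in caplog.messages)

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("timestamp,stream,value\n")
        with pytest.raises(ValueError, match="dialect"):
            pre.read_device_export([p], "garmin")

    def test_applewatch_single_file(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text(
            "timestamp,hr,steps\n"
            "2024-01-01 10:00,70,12\n"
            "2024-01-01 10:05,,30\n"
            "2024-01-01 10:10,75,\n"
        )
        rec = pre.read_device_export([p], "applewatch")
        assert len(rec.hr) == 2 and len(rec.steps) == 2
        assert rec.sleep_intervals == []


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

class TestBinning:
    def test_hr_mean_and_steps_rate(self):
        hr = pd.Series([70.0, 74.0], index=[T("2024-01-01 00:01"), T("2024-01-01 00:03")])
        steps = pd.Series([60.0], index=[T("2024-01-01 00:00")])
        b = pre.bin_records(make_records(hr, steps))
        assert b.hr[0] == pytest.approx(72.0)
        assert b.steps_per_min[0] == pytest.approx(12.0)

    def test_missing_hr_is_nan_not_zero(self):
        hr = pd.Series([70.0], index=[T("2024-01-01 00:00")])
        steps = pd.Series([10.0], index=[T("2024-01-01 00:20")])
        b = pre.bin_records(make_records(hr, steps))
        assert np.isnan(b.hr[1:]).all() and not np.isnan(b.hr[0])

    def test_cadence_invariance(self):
        """1-min and 1-s cadence encodings of the same signal give identical
        bin means (oracle: manual group-by), so oversampled periods do not
        dominate."""
        rng = np.random.default_rng(5)
        t0 = T("2024-01-01")
        t_min = t0 + pd.to_timedelta(np.arange(1000), unit="min")
        vals = 70 + 5 * np.sin(np.arange(1000) / 50) + rng.normal(0, 1, 1000)
        coarse = pd.Series(vals, index=t_min)
        # same per-minute values repeated at 1-s cadence
        t_sec = t0 + pd.to_timedelta(np.repeat(np.arange(1000) * 60, 60)
                                     + np.tile(np.arange(60), 1000), unit="s")
        fine = pd.Series(np.repeat(vals, 60), index=t_sec)
        b1 = pre.bin_records(make_records(coarse))
        b2 = pre.bin_records(make_records(fine))
        np.testing.assert_allclose(b1.hr, b2.hr, atol=1e-9)
        manual = coarse.groupby(coarse.index.floor("5min")).mean()
        np.testing.assert_allclose(b1.hr, manual.values, atol=1e-9)

    def test_total_steps_conserved(self):
        rng = np.random.default_rng(6)
        n = 300
        ts = T("2024-01-01") + pd.to_timedelta(
            np.cumsum(rng.integers(30, 400, n)), unit="s")
        steps = pd.Series(rng.integers(0, 50, n).astype(float), index=ts)
        b = pre.bin_records(make_records(steps=steps))
        assert np.sum(b.steps_per_min * b.bin_minutes) == pytest.approx(
            steps.sum(), rel=1e-9)

    def test_idempotent_on_binned_data(self):
        rng = np.random.default_rng(7)
        ts = pd.date_range("2024-01-01", periods=100, freq="5min")
        hr = pd.Series(rng.normal(70, 5, 100), index=ts)
        steps = pd.Series(rng.integers(0, 300, 100).astype(float), index=ts)
        b1 = pre.bin_records(make_records(hr, steps))
        b2 = pre.bin_records(b1.to_records())
        np.testing.assert_allclose(b1.hr, b2.hr, atol=1e-9)
        np.testing.assert_allclose(b1.steps_per_min, b2.steps_per_min, atol=1e-9)

    def test_bin_minutes_must_divide_hour(self):
        with pytest.raises(ValueError):
            pre.bin_records(make_records(), bin_minutes=7)

    def test_empty_records_valid(self):
        b = pre.bin_records(make_records())
        assert len(b) == 0


# ---------------------------------------------------------------------------
# sleep consolidation
# ---------------------------------------------------------------------------

class TestConsolidateSleep:
    def test_short_gap_merged(self):
        out = pre.consolidate_sleep([
            (T("2024-01-01 23:00"), T("2024-01-02 03:00")),
            (T("2024-01-02 04:00"), T("2024-01-02 07:30")),
        ])
        assert len(out) == 1
        assert out[0].start == T("2024-01-01 23:00")
        assert out[0].end == T("2024-01-02 07:30")
        assert out[0].midpoint == T("2024-01-02 03:15")

    def test_long_gap_not_merged(self):
        out = pre.consolidate_sleep([
            (T("2024-01-01 23:00"), T("2024-01-02 03:00")),
            (T("2024-01-02 06:00"), T("2024-01-02 08:00")),
        ])
        assert len(out) == 2

    def test_exact_two_hour_gap_kept_separate(self):
        out = pre.consolidate_sleep([
            (T("2024-01-01 23:00"), T("2024-01-02 03:00")),
            (T("2024-01-02 05:00"), T("2024-01-02 08:00")),
        ])
        assert len(out) == 2

    def test_night_shift_midpoint(self):
        # a ~7:30–13:30 daytime sleep is centred at 10:30
        [sp] = pre.consolidate_sleep([(T("2024-01-01 07:30"), T("2024-01-01 13:30"))])
        assert T("2024-01-01 10:29") <= sp.midpoint <= T("2024-01-01 10:31")

    def test_overlapping_merged_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="heartphase.preprocess"):
            out = pre.consolidate_sleep([
                (T("2024-01-01 23:00"), T("2024-01-02 03:00")),
                (T("2024-01-02 02:00"), T("2024-01-02 07:00")),
            ])
        assert len(out) == 1 and out[0].end == T("2024-01-02 07:00")
        assert any("overlap" in m for m in caplog.messages)


# ---------------------------------------------------------------------------
# wake-day segmentation and fit windows
# ---------------------------------------------------------------------------

def brute_force_days(binned, sleeps, min_sep_hours=2.0):
    """Reference: one pass over bins, cutting at separator sleeps."""
    bin_td = pd.Timedelta(minutes=binned.bin_minutes)
    seps = [s for s in sleeps if s.duration_hours > min_sep_hours]
    in_any_sleep = np.zeros(len(binned), dtype=bool)
    for s in sleeps:
        in_any_sleep |= (binned.bin_start < s.end) & (binned.bin_start + bin_td > s.start)
    in_sep = np.zeros(len(binned), dtype=bool)
    for s in seps:
        in_sep |= (binned.bin_start < s.end) & (binned.bin_start + bin_td > s.start)
    days, current = [], []
    for i in range(len(binned)):
        if in_sep[i]:
            if current:
                days.append(current)
                current = []
        elif not in_any_sleep[i]:
            current.append(i)
    if current:
        days.append(current)
    return days


class TestSegmentation:
    def regular(self, n_days=3):
        grid = pd.date_range("2024-01-01", periods=n_days * 288 + 1, freq="5min")
        hr = np.full(len(grid), 70.0)
        sleeps = pre.consolidate_sleep([
            (T("2024-01-01 23:00") + pd.Timedelta(days=i),
             T("2024-01-02 07:00") + pd.Timedelta(days=i))
            for i in range(n_days)
        ])
        binned = pre.BinnedSeries(grid, hr, np.zeros(len(grid)),
                                  np.ones(len(grid), bool))
        return binned, sleeps

    def test_regular_schedule_interior_days(self):
        binned, sleeps = self.regular(3)
        days = pre.segment_wake_days(binned, sleeps)
        interior = [d for d in days if d.bounded_left and d.bounded_right]
        assert len(interior) == 2
        for d in interior:
            dur = (d.end - d.start).total_seconds() / 3600
            assert 15.5 < dur < 16.5

    def test_nap_does_not_split_day(self):
        binned, sleeps = self.regular(2)
        nap = pre.consolidate_sleep([(T("2024-01-02 14:00"), T("2024-01-02 15:30"))])
        all_sleeps = sorted(sleeps + nap, key=lambda s: s.start)
        days = pre.segment_wake_days(binned, all_sleeps)
        assert len(days) == len(pre.segment_wake_days(binned, sleeps))
        # nap bins are excluded from the day even though it is not split
        day = [d for d in days if d.bounded_left and d.bounded_right][0]
        nap_bins = (binned.bin_start >= T("2024-01-02 14:00")) & (
            binned.bin_start < T("2024-01-02 15:30"))
        assert not np.intersect1d(day.bins, np.nonzero(nap_bins)[0]).size

    def test_matches_brute_force_on_shift_fixture(self):
        from heartphase import simulate as sim

        cfg = sim.shift_scenario_config(n_days=10, seed=13, shift_day=5)
        res = sim.simulate_records(cfg)
        sleeps = pre.consolidate_sleep(res.records.sleep_intervals)
        binned = pre.bin_records(res.records, sleeps=sleeps)
        days = pre.segment_wake_days(binned, sleeps)
        ref = brute_force_days(binned, sleeps)
        assert len(days) == len(ref)
        for d, r in zip(days, ref):
            np.testing.assert_array_equal(d.bins, r)

    def test_no_qualifying_sleep_single_flagged_span(self, caplog):
        binned, _ = self.regular(2)
        with caplog.at_level(logging.WARNING, logger="heartphase.preprocess"):
            days = pre.segment_wake_days(binned, [])
        assert len(days) == 1
        assert not (days[0].bounded_left and days[0].bounded_right)


class TestFitWindows:
    def test_window_count_and_no_sleep_observations(self, small_sim, small_windows):
        binned, sleeps, days, windows = small_windows
        n_interior_sleeps = len([s for s in sleeps if s.duration_hours > 2]) - 2
        assert len(windows) == n_interior_sleeps
        for w in windows:
            for sp in sleeps:
                t0 = w.day_before.start.normalize()
                lo = (sp.start - t0).total_seconds() / 3600
                hi = (sp.end - t0).total_seconds() / 3600
                inside = (w.t + 1e-9 >= lo) & (w.t < hi - 1e-9)
                assert not inside.any(), "observation inside a sleep period"

    def test_observation_floor_drops_window(self, small_sim):
        binned, sleeps, days, windows = pre.prepare_windows(
            small_sim.records, min_obs=10**6)
        assert windows == []

    def test_charging_gap_window_retained(self):
        from heartphase import simulate as sim

        cfg = sim.SimConfig(n_days=4, seed=3, charging_gaps=((2, 9.0, 6.0),))
        res = sim.simulate_records(cfg)
        binned, sleeps, days, windows = pre.prepare_windows(res.records)
        assert windows, "gap must not kill all windows"
        with_gap = [w for w in windows
                    if any(np.diff(np.rint(w.t * 12).astype(int)) > 60)]
        assert with_gap, "the 6-h gap should appear as missing bins inside a window"

    def test_manifest_shape(self, small_windows):
        _, _, _, windows = small_windows
        mf = pre.window_manifest(windows)
        assert list(mf.columns) == ["window_id", "day1_date", "sleep_midpoint", "n_obs"]
        assert (mf.n_obs >= 48).all()


class TestGapSleepInference:
    def test_charging_gap_treated_as_sleep(self):
        from heartphase import simulate as sim

        cfg = sim.SimConfig(n_days=4, seed=9)
        res = sim.simulate_records(cfg)
        # strip the sleep labels, as in an Apple-Watch-style export
        rec = pre.RawRecordSet(hr=res.records.hr, steps=res.records.steps[
            res.records.steps.values > 0], sleep_intervals=[])
        inferred = pre.infer_sleep_from_gaps(rec)
        assert len(inferred) >= 3
        for sp in inferred:
            assert sp.duration_hours >= 4.0
        binned, sleeps, days, windows = pre.prepare_windows(rec)
        assert len(windows) >= 1
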