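import warnings

import numpy as np
import pandas as pd
import pytest

from odbatools.accelerometry import (
    DEFAULT_COUNTS_PER_G,
    OdbaSeries,
    TriaxialSeries,
    aggregate,
    categorize_bouts,
    classify_hour,
    compute_window_odba,
    filter_deployment_days,
    threshold_sensitivity,
)


def make_series(ax, ay, az, rate_hz=50.0, start="2018-05-01"):
    n = len(ax)
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) / rate_hz, unit="s")
    return TriaxialSeries(
        individual_id="t",
        samples=pd.DataFrame({"timestamp": ts, "ax": ax, "ay": ay, "az": az}),
    )


def brute_force_window_odba(ax, ay, az, counts_per_g):
    """Independent evaluation: mean minus (max+min)/2 per channel, L1 norm."""
    total = 0.0
    for ch in (ax, ay, az):
        ch = [float(v) for v in ch]
        mean = sum(ch) / len(ch)
        midpoint = (max(ch) + min(ch)) / 2.0
        total += abs((mean - midpoint) / counts_per_g)
    return total


class TestWindowOdba:
    def test_constant_channels_zero(self):
        n = 200
        s = make_series(np.full(n, 123), np.full(n, -40), np.full(n, 16384))
        out = compute_window_odba(s)
        np.testing.assert_array_equal(out["odba"], 0.0)

    def test_symmetric_alternation_zero(self):
        # one channel alternating +/-k around 0: mean 0, midpoint 0
        n = 200
        k = 500
        alt = np.tile([k, -k], n // 2)
        out = compute_window_odba(make_series(alt, np.zeros(n), np.full(n, 7)))
        np.testing.assert_allclose(out["odba"], 0.0, atol=1e-15)

    def test_exact_match_with_brute_force(self, rng):
        n_windows, n = 100, 100
        ax = rng.integers(-2000, 2000, n_windows * n)
        ay = rng.integers(-2000, 2000, n_windows * n)
        az = rng.integers(14000, 19000, n_windows * n)
        out = compute_window_odba(make_series(ax, ay, az))
        for w in range(n_windows):
            sl = slice(w * n, (w + 1) * n)
            expected = brute_force_window_odba(ax[sl], ay[sl], az[sl],
                                               DEFAULT_COUNTS_PER_G)
            assert out["odba"].iloc[w] == pytest.approx(expected, abs=1e-15)

    def test_scale_equivariance(self, rng):
        n = 400
        ax = rng.integers(-1000, 1000, n)
        base = compute_window_odba(make_series(ax, np.zeros(n), np.zeros(n)))
        scaled = compute_window_odba(make_series(3 * ax, np.zeros(n), np.zeros(n)))
        np.testing.assert_allclose(scaled["odba"], 3 * base["odba"], rtol=1e-12)

    def test_empty_and_bad_window_rejected(self):
        s = make_series(np.zeros(10), np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            compute_window_odba(s, window_s=0)
        with pytest.raises(ValueError):
            compute_window_odba(TriaxialSeries("e", pd.DataFrame(
                columns=["timestamp", "ax", "ay", "az"])))


class TestAggregate:
    def _windows(self, values, start="2018-05-01 00:00"):
        ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(values)) * 2, unit="s")
        return pd.DataFrame({"window_start": ts, "odba": values})

    def test_constant_minute_and_hour(self):
        w = self._windows(np.full(30, 0.1))  # one full minute of 2 s windows
        out = aggregate(w)
        assert out.minute["odba"].iloc[0] == pytest.approx(0.1)
        assert out.hourly["odba"].iloc[0] == pytest.approx(3.0)

    def test_single_window_minute(self):
        out = aggregate(self._windows([0.42]))
        assert out.minute["odba"].iloc[0] == pytest.approx(0.42)
        assert not out.minute["complete"].iloc[0]

    def test_hour_sums_match_brute_force_regrouping(self, rng):
        vals = rng.uniform(0, 1, 3 * 1800)  # three full hours
        w = self._windows(vals)
        out = aggregate(w)
        grouped = w.groupby(w["window_start"].dt.floor("h"))["odba"].sum()
        np.testing.assert_allclose(out.hourly["odba"].to_numpy(),
                                   grouped.to_numpy(), rtol=1e-12)
        # conservation: total over hours equals total over windows
        assert out.hourly["odba"].sum() == pytest.approx(vals.sum())


class TestClassifyHour:
    def _minutes(self, odba_values):
        ts = pd.Timestamp("2018-05-01 00:00") + pd.to_timedelta(
            np.arange(len(odba_values)), unit="min")
        return pd.DataFrame({"minute_start": ts, "odba": odba_values})

    def test_31_minutes_above_is_active(self):
        vals = [0.29] * 31 + [0.0] * 29
        out = classify_hour(self._minutes(vals), threshold=0.28)
        assert bool(out["active"].iloc[0])

    def test_exactly_30_minutes_is_inactive(self):
        vals = [0.29] * 30 + [0.0] * 30
        out = classify_hour(self._minutes(vals), threshold=0.28)
        assert not bool(out["active"].iloc[0])

    def test_values_at_threshold_are_inactive(self):
        out = classify_hour(self._minutes([0.28] * 60), threshold=0.28)
        assert not bool(out["active"].iloc[0])

    def test_short_hours_flagged_incomplete(self):
        out = classify_hour(self._minutes([0.5] * 45))
        assert not bool(out["complete"].iloc[0])


class TestBouts:
    def test_single_contiguous_run(self):
        seq = np.zeros(1440, dtype=bool)
        seq[600:900] = True
        assert categorize_bouts(seq) == ("single_bout", 1)

    def test_gap_resumed(self):
        seq = np.zeros(1440, dtype=bool)
        seq[300:500] = True     # 200 min active
        seq[590:690] = True     # 90 min gap, then 100 min active
        assert categorize_bouts(seq) == ("gap_resumed", 2)

    def test_short_pause_does_not_break_bout(self):
        seq = np.zeros(1440, dtype=bool)
        seq[300:400] = True
        seq[430:500] = True     # 30 min pause < 60
        assert categorize_bouts(seq)[0] == "single_bout"

    def test_no_activity_is_other(self):
        assert categorize_bouts(np.zeros(1440, dtype=bool)) == ("other", 0)


class TestThresholdSensitivity:
    def test_bimodal_recommendation_between_modes(self, rng):
        low = rng.normal(0.05, 0.01, 500).clip(0.001)
        high = rng.normal(0.6, 0.05, 500)
        values = np.concatenate([low, high])
        scan = threshold_sensitivity(values, np.linspace(0.02, 0.9, 45))
        # recommendation separates the two modes
        assert 0.05 < scan.recommended < 0.6
        assert (low < scan.recommended).all() and (high > scan.recommended).all()

    def test_candidates_above_maximum(self, rng):
        values = rng.uniform(0, 0.1, 100)
        scan = threshold_sensitivity(values, [0.5, 0.6, 0.7])
        assert (scan.table["active_minutes"] == 0).all()

    def test_active_minutes_monotone_in_threshold(self, rng):
        values = rng.exponential(0.3, 1000)
        scan = threshold_sensitivity(values, np.linspace(0.05, 1.0, 20))
        active = scan.table.sort_values("threshold")["active_minutes"].to_numpy()
        assert (np.diff(active) <= 0).all()

    def test_constant_series_gives_no_recommendation(self):
        scan = threshold_sensitivity(np.full(100, 0.3), [0.1, 0.5])
        assert scan.recommended is None


class TestDeploymentFilter:
    def _hours(self, start, n):
        return pd.DataFrame({"hour_start": pd.date_range(start, periods=n, freq="h")})

    def test_seven_day_deployment_keeps_five(self):
        # deployment touching 7 noon-to-noon days: first and last removed
        f = self._hours("2018-05-01 15:00", 164)
        out = filter_deployment_days(f, "2018-05-01 15:00", "2018-05-08 10:00")
        from odbatools.ephemeris import assign_nights
        nights = set(assign_nights(out["hour_start"]))
        assert len(nights) == 5

    def test_two_day_deployment_empty_with_warning(self):
        f = self._hours("2018-05-01 15:00", 44)
        with pytest.warns(UserWarning, match="too short"):
            out = filter_deployment_days(f, "2018-05-01 15:00", "2018-05-03 10:00")
        assert len(out) == 0

    def test_matches_set_difference_oracle(self):
        from odbatools.ephemeris import assign_nights
        f = self._hours("2018-05-01 09:00", 8 * 24)
        start, end = "2018-05-01 09:00", "2018-05-09 08:00"
        out = filter_deployment_days(f, start, end)
        all_nights = set(assign_nights(f["hour_start"]))
        boundary = {assign_nights(pd.Series([pd.Timestamp(start)])).iloc[0],
                    assign_nights(pd.Series([pd.Timestamp(end)])).iloc[0]}
        expected = {n for n in all_nights - boundary
                    if min(boundary) < n < max(boundary)}
        assert set(assign_nights(out["hour_start"])) == expected
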