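"""Fits (raw/optimized, linear/logarithmic) and derived growth metrics."""

import numpy as np
import pandas as pd
import pytest

from myceliotrack.metrics import (
    DerivedSummary,
    derive_summary,
    fit_series,
    hyphal_track_metrics,
    position_metrics,
)
from myceliotrack.tracking import HyphaTrack, TrackRecord


def brute_force_window(t, y, threshold=0.9, min_points=3):
    """Independent O(n²) oracle for the optimized-window selection."""
    best = None
    n = len(t)
    for i in range(n):
        for j in range(i + min_points, n + 1):
            tt, yy = t[i:j], y[i:j]
            if np.ptp(tt) == 0 or np.ptp(yy) == 0:
                continue
            slope, intercept = np.polyfit(tt, yy, 1)
            resid = yy - (slope * tt + intercept)
            r2 = 1 - np.sum(resid ** 2) / np.sum((yy - yy.mean()) ** 2)
            if r2 > threshold:
                cand = (j - i, r2, -i)
                if best is None or cand > best[:3]:
                    best = (j - i, r2, -i, i, j, slope)
    return best


def _toy_track(lengths, start=0, track_id=0):
    t = HyphaTrack(track_id=track_id)
    for i, L in enumerate(lengths):
        t.records.append(TrackRecord(
            frame=start + i, tip_node=1, anchor_node=0, path_nodes=(0, 1),
            hop_count=1, length_um=float(L), tip_pos_um=(0.0, float(L)),
        ))
    t.end_reason = "end-of-stack"
    return t


class TestFitSeries:
    def test_exact_exponential_log_raw(self):
        t = np.linspace(0, 10, 20)
        y = np.exp(0.45 * t) * 3.0
        fit = fit_series(t, y, "logarithmic", "raw")
        assert fit.slope == pytest.approx(0.45, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_exponential_raw_equals_optimized(self):
        t = np.linspace(0, 8, 25)
        y = 2.0 * np.exp(0.3 * t)
        raw = fit_series(t, y, "logarithmic", "raw")
        opt = fit_series(t, y, "logarithmic", "optimized")
        assert opt.slope == pytest.approx(raw.slope, abs=1e-12)
        assert opt.n_points == raw.n_points

    def test_zero_lag_then_exponential_recovers_rate(self):
        """Pre-germination zeros are dropped by the log transform, so the
        optimized window is exactly the exponential phase."""
        t = np.arange(20.0)
        y = np.concatenate([np.zeros(8), np.exp(0.5 * (np.arange(12) + 1))])
        fit = fit_series(t, y, "logarithmic", "optimized")
        assert fit.n_points == 12
        assert fit.slope == pytest.approx(0.5, abs=1e-9)

    def test_constant_series_degenerate(self):
        fit = fit_series(np.arange(5.0), np.full(5, 3.0), "linear", "raw")
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0
        assert fit.degenerate

    def test_too_few_points_missing(self):
        assert fit_series([0, 1], [1, 2], "linear", "raw") is None
        # only 2 positive values for the log transform
        assert fit_series([0, 1, 2, 3], [0, 0, 1, 2], "logarithmic", "raw") is None

    def test_no_qualifying_window_missing(self):
        t = np.arange(12.0)
        y = np.array([0.0, 1.0] * 6)  # alternating: every window has low R²
        assert fit_series(t, y, "linear", "optimized") is None

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = rng.integers(5, 50)
            t = np.sort(rng.uniform(0, 24, n))
            kind = rng.integers(0, 3)
            if kind == 0:
                y = rng.normal(0, 1, n) + 0.3 * t
            elif kind == 1:
                y = np.exp(0.2 * t + rng.normal(0, 0.4, n))
            else:
                y = np.cumsum(rng.normal(0, 1, n))
            fit = fit_series(t, y, "linear", "optimized")
            oracle = brute_force_window(t, y)
            if oracle is None:
                assert fit is None
            else:
                assert fit is not None
                _, _, _, i, j, slope = oracle
                assert fit.n_points == j - i
                assert fit.t_start_h == pytest.approx(t[i])
                assert fit.slope == pytest.approx(slope, rel=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            fit_series([0, 1, 2], [1, 2, 3], "quadratic", "raw")
        with pytest.raises(ValueError):
            fit_series([0, 1, 2], [1, 2, 3], "linear", "best")


class TestTrackMetrics:
    def test_relative_lengths_and_slope(self):
        track = _toy_track([5.0, 8.0, 11.0])
        ts = np.array([0.0, 3600.0, 7200.0])
        summary, points = hyphal_track_metrics([track], ts)
        np.testing.assert_allclose(points["relative_length_um"], [0, 3, 6])
        row = summary.iloc[0]
        assert row["absolute_linear_raw_slope"] == pytest.approx(3.0)
        assert row["tip_elongation_rate_um_h"] == pytest.approx(3.0)
        assert row["min_length_um"] == 5.0 and row["max_length_um"] == 11.0
        assert row["duration_s"] == 7200.0 and row["n_time_points"] == 3

    def test_single_record_track_fits_missing(self):
        track = _toy_track([5.0])
        track.flagged_short = True
        summary, points = hyphal_track_metrics([track], np.array([0.0]))
        assert len(points) == 1
        assert np.isnan(summary.iloc[0]["absolute_linear_optimized_slope"])

    def test_successor_node_ids_emitted(self):
        track = _toy_track([5.0, 8.0])
        _, points = hyphal_track_metrics([track], np.array([0.0, 60.0]))
        assert points.iloc[0]["successor_node_ids"] == "0,1"
        assert points.iloc[1]["successor_node_ids"] == ""


class TestPositionMetrics:
    def test_empty_and_y_shaped_frames(self, small_run):
        truth, stack, masks, result = small_run
        df = result.position_timeseries
        assert set(df.columns) >= {
            "timestamp_s", "covered_area_um2", "total_length_um",
            "branching_count", "tip_count", "hyphal_growth_unit_um",
        }
        # pre-germination frame: essentially empty (spore only)
        first = df.iloc[0]
        assert first["total_length_um"] < 3.0
        assert first["tip_count"] == 0
        # growth frames: covered area equals mask sum * calibration²
        i = len(df) - 1
        expected = result.masks[i].mask.sum() * stack.calibration ** 2
        assert df.iloc[i]["covered_area_um2"] == pytest.approx(expected)

    def test_rendered_y_mycelium_counts(self):
        import myceliotrack as mt
        frame = np.full((128, 128), 100.0)
        mask = np.zeros((128, 128), dtype=bool)
        mask[64, 20:64] = True
        for i in range(40):
            mask[64 - i, 64 + i] = True
            mask[64 + i, 64 + i] = True
        frame[mask] -= 40.0
        bm = mt.BinaryMask(mask=mask)
        from myceliotrack.skeleton_graph import Skeleton, build_graph
        g = build_graph(Skeleton(mask), calibration=0.65)
        stack = mt.ImageStack(frame[None], [0.0], 0.65)
        df = position_metrics([g], [bm], stack)
        assert df.iloc[0]["branching_count"] == 1
        assert df.iloc[0]["tip_count"] == 3


class TestDeriveSummary:
    def _series(self, t_h, y):
        return pd.DataFrame({
            "frame": np.arange(len(t_h)),
            "timestamp_h": t_h,
            "total_length_um": y,
        })

    def test_lag_then_exponential_recovers_mu_and_delay(self):
        t = np.arange(0, 24, 1 / 3)
        y = np.where(t > 12.0, 5.0 * np.exp(0.45 * (t - 12.0)), 0.0)
        first = int(np.argmax(y > 0))
        track = _toy_track([5.0, 8.0, 11.0], start=first)
        series = self._series(t, y)
        s = derive_summary(series, [track])
        assert s.mycelium_growth_rate_h == pytest.approx(0.45, abs=0.01)
        assert abs(s.germination_delay_h - 12.0) <= 1 / 3
        assert s.first_nonzero_length_h == pytest.approx(t[first])

    def test_empty_position_all_missing(self):
        s = derive_summary(self._series(np.arange(5.0), np.zeros(5)), [])
        assert s.mycelium_growth_rate_h is None
        assert s.germination_delay_h is None
        assert s.tip_rate_mean_um_h is None

    def test_tip_rate_mean_and_sample_sd(self):
        t1 = _toy_track(list(np.arange(5.0) * 10.0), track_id=0)   # 10 µm/h
        t2 = _toy_track(list(np.arange(5.0) * 20.0), track_id=1)   # 20 µm/h
        series = self._series(np.arange(5.0), np.arange(5.0) * 30.0 + 1)
        s = derive_summary(series, [t1, t2])
        assert s.tip_rate_mean_um_h == pytest.approx(15.0)
        assert s.tip_rate_sd_um_h == pytest.approx(5 * np.sqrt(2), rel=1e-9)

    def test_spurious_tracks_ignored_for_delay(self):
        speck = _toy_track([0.5, 0.6, 0.5], start=0, track_id=0)
        speck.flagged_spurious = True
        real = _toy_track([5.0, 9.0, 13.0], start=6, track_id=1)
        series = self._series(np.arange(10.0), np.linspace(0, 20, 10))
        s = derive_summary(series, [speck, real])
        assert s.germination_delay_h == pytest.approx(6.0)
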