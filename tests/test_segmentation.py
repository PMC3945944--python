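"""Surface-offset correction, dive detection, and phase segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from foragedive.segmentation import (NoSurfaceRecordsError,
                                     correct_surface_offset, detect_dives,
                                     segment_dives, segment_phases)
from foragedive.series import DepthSeries


def trapezoid(depth_max=30.0, rate=1.0, bottom=60, lead=5, tail=5):
    """Surface - linear descent - flat bottom - linear ascent - surface."""
    n_t = int(round(depth_max / rate))
    d = ([0.0] * lead + [rate * i for i in range(0, n_t + 1)]
         + [depth_max] * bottom + [rate * i for i in range(n_t - 1, -1, -1)]
         + [0.0] * tail)
    return np.asarray(d)


class TestSegmentPhases:
    def test_trapezoid_phases_and_rates(self):
        d = trapezoid(30.0, 1.0, bottom=60, lead=0, tail=0)
        i_desc, i_asc = segment_phases(d)
        assert i_desc == 30
        assert i_asc - i_desc == 60
        assert len(d) - 1 - i_asc == 30
        assert d[i_desc] / i_desc == pytest.approx(1.0)

    def test_v_dive_has_negligible_bottom(self):
        n = 30
        d = np.array([1.0 * i for i in range(n + 1)] +
                     [1.0 * i for i in range(n - 1, -1, -1)])
        i_desc, i_asc = segment_phases(d)
        assert 0 <= i_asc - i_desc <= 2

    def test_shallow_plateau_tolerated_as_step(self):
        # 5-s plateau at 10 m (33 % of 30 m): descent continues to 30 m
        d = ([1.0 * i for i in range(11)] + [10.0] * 5
             + [10.0 + i for i in range(1, 21)] + [30.0] * 30
             + [30.0 - i for i in range(1, 31)])
        d = np.asarray(d)
        i_desc, _ = segment_phases(d)
        assert d[i_desc] == pytest.approx(30.0)

    def test_long_plateau_initiates_bottom_regardless_of_depth(self):
        # 10-s plateau at 10 m of a 30-m dive: slow run >= 8 s ends descent
        d = ([1.0 * i for i in range(11)] + [10.0] * 10
             + [10.0 + i for i in range(1, 21)] + [30.0] * 20
             + [30.0 - i for i in range(1, 31)])
        i_desc, _ = segment_phases(np.asarray(d))
        assert d[i_desc] == pytest.approx(10.0)

    def test_durations_sum_to_dive_duration(self, clean_segmented):
        _, dives, _ = clean_segmented
        ok = dives[dives.deep & ~dives.degenerate]
        total = ok.descent_duration + ok.bottom_duration + ok.ascent_duration
        assert np.all(np.abs(total - ok.dive_duration) <= 1.0)


class TestDetectDives:
    def test_below_threshold_series_has_no_dives(self):
        s = DepthSeries("x", np.arange(100.0), np.full(100, 2.9))
        assert detect_dives(s) == []

    def test_two_rectangular_excursions(self):
        d = np.zeros(300)
        d[50:100] = 20.0
        d[200:240] = 20.0
        s = DepthSeries("x", np.arange(300.0), d)
        pairs = detect_dives(s)
        assert len(pairs) == 2
        df = segment_dives(s)
        assert df["post_dive_interval"].iloc[0] == pytest.approx(100.0, abs=2)

    def test_single_deep_excursion_max_depth(self):
        d = np.zeros(200)
        d[80:120] = 50.0
        s = DepthSeries("x", np.arange(200.0), d)
        df = segment_dives(s)
        assert len(df) == 1
        assert df["max_depth"].iloc[0] == 50.0

    def test_agrees_with_bruteforce_scan_and_idempotent(self, small_trip):
        _, depth, _, _ = small_trip
        from foragedive.segmentation import correct_surface_offset
        corr = correct_surface_offset(depth)
        pairs = detect_dives(corr)
        assert pairs == oracles.dive_runs(corr.depth)
        assert pairs == detect_dives(corr)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_oracle_on_random_step_profiles(self, seed):
        rng = np.random.default_rng(seed)
        d = np.abs(np.cumsum(rng.normal(0, 2.0, 200)))
        d[::17] = 0.0  # guarantee surface returns
        s = DepthSeries("x", np.arange(200.0), d)
        assert detect_dives(s) == oracles.dive_runs(d)


class TestSurfaceOffset:
    def test_constant_offset_removed(self, clean_trip):
        _, depth, _, truth = clean_trip
        shifted = DepthSeries("x", depth.time, depth.depth + 0.5)
        corr = correct_surface_offset(shifted)
        surf = _surface_mask(truth)
        assert np.abs(corr.depth[surf]).max() < 0.05

    def test_linear_drift_removed(self, clean_trip):
        _, depth, _, truth = clean_trip
        t = depth.time
        drifted = DepthSeries("x", t, depth.depth + 1.0 * t / t[-1])
        corr = correct_surface_offset(drifted)
        inner = slice(int(t[-1] * 0.05), int(t[-1] * 0.95))
        assert np.abs(corr.depth[inner] - depth.depth[inner]).max() < 0.1

    def test_already_zeroed_series_nearly_unchanged(self, clean_trip):
        _, depth, _, _ = clean_trip
        corr = correct_surface_offset(depth)
        assert np.abs(corr.depth - depth.depth).max() < 0.05

    def test_diveless_series_raises(self):
        s = DepthSeries("x", np.arange(500.0), np.zeros(500))
        with pytest.raises(NoSurfaceRecordsError):
            correct_surface_offset(s)


def _surface_mask(truth):
    T = int(truth.dives["end_s"].max()) + 100
    mask = np.ones(T, dtype=bool)
    for _, row in truth.dives.iterrows():
        mask[int(row.start_s):int(row.end_s) + 1] = False
    return np.where(mask)[0]


class TestTruthRecovery:
    def test_noise_free_boundaries_exact(self, clean_segmented):
        _, _, m = clean_segmented
        deep = m[m.deep & ~m.degenerate].dropna(subset=["descent_end_s_t"])
        assert len(deep) > 50
        assert ((deep.descent_end_s - deep.descent_end_s_t).abs() < 1e-9).mean() >= 0.99
        assert ((deep.ascent_start_s - deep.ascent_start_s_t).abs() < 1e-9).mean() >= 0.99

    def test_noisy_boundaries_within_two_seconds(self, small_trip):
        from conftest import match_truth
        _, depth, _, truth = small_trip
        corr = correct_surface_offset(depth)
        m = match_truth(segment_dives(corr), truth.dives)
        deep = m[m.deep & ~m.degenerate].dropna(subset=["descent_end_s_t"])
        assert len(deep) > 100
        assert ((deep.descent_end_s - deep.descent_end_s_t).abs() <= 2).mean() >= 0.95
        assert ((deep.ascent_start_s - deep.ascent_start_s_t).abs() <= 2).mean() >= 0.95
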