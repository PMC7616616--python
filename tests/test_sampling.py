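"""Extended-CAIPI shot trajectories, sampling metrics and greedy optimization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import convolve2d

from selfnav3d.sampling import (
    SamplingConfig,
    SamplingError,
    SamplingMaskSet,
    ShotParams,
    ShotPattern,
    basic_shot_trajectory,
    gap_metric,
    greedy_optimize,
    kz0_traversal_shot,
    nav_distance,
    overlap_metric,
    per_shot_undersampling,
    search_space,
    selfnav_acceleration,
)


def config(ny=180, nkz=12, nshot=12, **kw):
    return SamplingConfig(ny=ny, nkz=nkz, nshot=nshot, **kw)


class TestBasicTrajectory:
    def test_period_follows_band_width(self):
        cfg = config()
        assert cfg.w == 7
        assert cfg.period == 12

    def test_minimal_band_alternates(self):
        cfg = config(nkz=2, nshot=2)
        shot = basic_shot_trajectory(cfg, ShotParams(0, 0, 0))
        assert list(shot.lines[:4, 1]) == [0, 1, 0, 1]

    def test_triangle_sequence_and_selfnav_rate(self):
        cfg = config()
        shot = basic_shot_trajectory(cfg, ShotParams(0, 0, 0))
        assert list(shot.lines[:9, 1]) == [0, 1, 2, 3, 4, 5, 6, 5, 4]
        # central plane (kz=6) touched exactly once per 12 acquired lines
        nav = shot.selfnav_lines(cfg)
        assert nav.shape[0] == shot.lines.shape[0] // cfg.period

    def test_band_visits_every_plane_each_period(self):
        cfg = config()
        for sp in range(cfg.period):
            shot = basic_shot_trajectory(cfg, ShotParams(0, 3, sp))
            first_period = shot.lines[: cfg.period, 1]
            assert set(first_period) == set(range(3, 3 + cfg.w))

    def test_parameter_validation(self):
        cfg = config()
        with pytest.raises(SamplingError):
            basic_shot_trajectory(cfg, ShotParams(3, 0, 0))
        with pytest.raises(SamplingError):
            basic_shot_trajectory(cfg, ShotParams(0, 6, 0))
        with pytest.raises(SamplingError):
            SamplingConfig(ny=180, nkz=1, nshot=1)

    @settings(max_examples=50, deadline=None)
    @given(
        nkz=st.integers(4, 16),
        s_ky=st.integers(0, 2),
        s_p=st.integers(0, 30),
        s_kz=st.integers(0, 20),
    )
    def test_pattern_invariants_hold_for_all_parameters(self, nkz, s_ky, s_kz, s_p):
        cfg = SamplingConfig(ny=60, nkz=nkz, nshot=1, ry=3)
        s_kz = s_kz % (nkz - cfg.w + 1)
        s_p = s_p % cfg.period
        shot = basic_shot_trajectory(cfg, ShotParams(s_ky, s_kz, s_p))
        ky, kz = shot.lines[:, 0], shot.lines[:, 1]
        assert np.all((kz >= s_kz) & (kz <= s_kz + cfg.w - 1))
        assert np.all(ky % cfg.ry == s_ky) and len(set(ky)) == len(ky)
        assert (kz == cfg.kz_center).any()  # at least one self-navigation point


class TestTraversalShot:
    def test_line_count_and_plane(self):
        cfg = config()
        shot = kz0_traversal_shot(cfg, s_ky=0)
        assert shot.lines.shape[0] == 60
        assert np.all(shot.lines[:, 1] == 6)
        assert shot.is_kz0_traversal

    def test_nav_distance_zero_with_center_line(self):
        cfg = config()
        assert nav_distance(kz0_traversal_shot(cfg, 0), cfg) == 0.0

    def test_ky_progression(self):
        cfg = config()
        shot = kz0_traversal_shot(cfg, s_ky=1)
        assert list(shot.lines[:3, 0]) == [1, 4, 7]
        assert shot.lines[-1, 0] == 178


class TestMetrics:
    def test_overlap_identical_and_disjoint(self):
        cfg = config(ny=45, nkz=12, nshot=2, ry=1)
        m = np.zeros((45, 12), np.uint8)
        m[::1, 3] = 1  # 45 points
        masks = SamplingMaskSet(np.stack([m, m]))
        assert overlap_metric(masks, 2) == 45
        m2 = np.zeros_like(m)
        m2[:, 5] = 1
        assert overlap_metric(SamplingMaskSet(np.stack([m, m2])), 2) == 0

    def test_gap_extremes(self):
        full = SamplingMaskSet(np.ones((1, 20, 12), np.uint8))
        assert gap_metric(full, 1) == 0
        empty = SamplingMaskSet(np.zeros((1, 20, 12), np.uint8))
        assert gap_metric(empty, 1) == 18 * 10

    def test_gap_single_center_cell(self):
        m = np.zeros((1, 6, 6), np.uint8)
        m[0, 3, 3] = 1
        # of the 16 valid windows, those containing (3,3) are not gaps
        assert gap_metric(SamplingMaskSet(m), 1) == 16 - 9

    def test_metrics_match_naive_counting_on_random_masks(self, rng):
        for _ in range(100):
            masks = (rng.random((3, 20, 12)) < 0.15).astype(np.uint8)
            ms = SamplingMaskSet(masks)
            comb = masks.sum(axis=0)
            assert overlap_metric(ms, 3) == int((comb > 1).sum())
            naive_gaps = sum(
                1
                for i in range(18)
                for j in range(10)
                if comb[i : i + 3, j : j + 3].sum() == 0
            )
            assert gap_metric(ms, 3) == naive_gaps

    def test_index_validation(self):
        ms = SamplingMaskSet(np.zeros((2, 20, 12), np.uint8))
        with pytest.raises(SamplingError):
            overlap_metric(ms, 0)
        with pytest.raises(SamplingError):
            gap_metric(ms, 3)

    def test_nav_distance_axis_aligned(self):
        cfg = config()
        lines = np.array([[cfg.ky_center + 15, cfg.kz_center]])
        shot = ShotPattern(ShotParams(0, 0, 0), lines)
        assert nav_distance(shot, cfg) == 15.0

    def test_nav_distance_requires_selfnav_point(self):
        cfg = config()
        shot = ShotPattern(ShotParams(0, 0, 0), np.array([[0, 0]]))
        with pytest.raises(SamplingError):
            nav_distance(shot, cfg)


class TestGreedy:
    def test_deterministic(self, design_180):
        cfg, patterns = design_180
        again = greedy_optimize(cfg)
        for a, b in zip(patterns, again):
            assert a.params == b.params
            assert np.array_equal(a.lines, b.lines)

    @pytest.mark.parametrize("ny", [180, 204])
    def test_constraints_and_quality(self, ny):
        cfg = config(ny=ny)
        patterns = greedy_optimize(cfg)
        assert len(patterns) == 12
        assert all(nav_distance(p, cfg) <= cfg.dmax for p in patterns)
        ms = SamplingMaskSet.from_patterns(patterns, cfg)
        counts = set(np.unique(ms.combined))
        assert counts <= {0, 1, 2}
        total = int(ms.combined.sum())
        assert overlap_metric(ms, 12) / total < 0.05

    def test_infeasible_dmax_raises(self):
        cfg = config(dmax=-1.0)
        with pytest.raises(SamplingError, match="step"):
            greedy_optimize(cfg)

    def test_additive_cost_variant_satisfies_constraint(self):
        cfg = config()
        patterns = greedy_optimize(cfg, nav_cost="additive")
        assert all(nav_distance(p, cfg) <= cfg.dmax for p in patterns)

    def test_search_space_bookkeeping(self):
        space = search_space(config())
        assert space["per_step"] == 6 * 3 * 12
        assert space["greedy_total"] == 216 * 11
        assert space["joint_total"] == pytest.approx(4.78e25, rel=0.01)


class TestAccelerationFactors:
    def test_single_and_double_crossing(self):
        cfg = config()
        once = basic_shot_trajectory(cfg, ShotParams(0, 0, 0))  # extremum touch
        assert selfnav_acceleration(once, cfg) == 36.0
        twice = basic_shot_trajectory(cfg, ShotParams(0, 3, 0))  # mid-band plane
        assert selfnav_acceleration(twice, cfg) == 18.0

    def test_traversal_equals_ry(self):
        cfg = config()
        assert selfnav_acceleration(kz0_traversal_shot(cfg, 0), cfg) == 3.0

    def test_per_shot_undersampling(self):
        assert per_shot_undersampling(config(ny=180, nkz=10, nshot=10)) == 30.0
        assert per_shot_undersampling(config(ny=180, nkz=12, nshot=12)) == 36.0
        assert per_shot_undersampling(SamplingConfig(ny=64, nkz=4, nshot=1, ry=1)) == 4.0


class TestPartialFourier:
    def test_masks_restricted_to_acquired_range(self):
        cfg = config(pf=0.75)
        shot = basic_shot_trajectory(cfg, ShotParams(0, 0, 0))
        assert shot.lines[:, 0].max() < round(0.75 * 180)
        assert shot.lines.shape[0] == len(range(0, 135, 3))
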