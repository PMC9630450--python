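"""Per-frame motion statistics: oracles, sign conventions, gating."""

import numpy as np
import pytest

from astromigrate.config import AnalysisConfig
from astromigrate.datatypes import CorticalFrame, Track
from astromigrate.trajectory import (angles_to_radial, compare_speed_distributions,
                                     directional_changes, frame_steps, motile_filter,
                                     polar_summary, wrap_deg)

from conftest import random_track

RIGHT = CorticalFrame(radial_axis=(0.0, 1.0), upper_border_um=-100.0,
                      lower_border_um=0.0, hemisphere="right")
LEFT = CorticalFrame(radial_axis=(0.0, 1.0), upper_border_um=-100.0,
                     lower_border_um=0.0, hemisphere="left")


def _track(points, dt=0.5, hemisphere="right"):
    pts = np.asarray(points, dtype=float)
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    return Track(track_id="t", hemisphere=hemisphere,
                 t_h=np.arange(len(pts)) * dt, xyz_um=pts)


class TestWrap:
    def test_range_and_idempotence(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-1000, 1000, 500)
        w = wrap_deg(a)
        assert np.all(w > -180.0) and np.all(w <= 180.0)
        assert np.allclose(wrap_deg(w), w)

    def test_boundary(self):
        assert wrap_deg(180.0) == 180.0
        assert wrap_deg(-180.0) == 180.0
        assert wrap_deg(540.0) == 180.0


class TestFrameSteps:
    def test_stationary_track(self):
        tr = _track(np.tile([50.0, 50.0], (10, 1)))
        steps = frame_steps(tr)
        assert all(s.speed_umh == 0.0 and not s.gated for s in steps)
        assert all(s.direction_deg is None for s in steps)

    def test_gate_is_strict(self):
        # 5 um in 0.5 h = exactly 10 um/h: NOT gated ("more than 10")
        tr = _track([[0.0, 0.0], [5.0, 0.0]])
        (step,) = frame_steps(tr)
        assert step.speed_umh == pytest.approx(10.0)
        assert not step.gated
        tr2 = _track([[0.0, 0.0], [5.1, 0.0]])
        assert frame_steps(tr2)[0].gated

    def test_duplicate_timestamps_rejected_with_index(self):
        with pytest.raises(ValueError, match="sample 2"):
            Track(track_id="x", hemisphere="right", t_h=[0.0, 0.5, 0.5],
                  xyz_um=np.zeros((3, 3)))

    def test_speeds_match_brute_force(self):
        rng = np.random.default_rng(42)
        tr = random_track(rng, n=40)
        steps = frame_steps(tr)
        for i, s in enumerate(steps):
            d = tr.xyz_um[i + 1] - tr.xyz_um[i]
            dt = tr.t_h[i + 1] - tr.t_h[i]
            assert s.displacement_um == pytest.approx(np.sqrt((d ** 2).sum()))
            assert s.speed_umh == pytest.approx(np.sqrt((d ** 2).sum()) / dt)
            expected_dir = np.degrees(np.arctan2(d[1], d[0]))
            assert s.direction_deg == pytest.approx(expected_dir)

    def test_planar_speed_mode(self):
        tr = _track([[0.0, 0.0, 0.0], [3.0, 0.0, 4.0]])
        assert frame_steps(tr)[0].speed_umh == pytest.approx(10.0)
        assert frame_steps(tr, use_z=False)[0].speed_umh == pytest.approx(6.0)

    def test_gate_monotonicity(self):
        rng = np.random.default_rng(1)
        tr = random_track(rng, n=50)
        counts = [sum(s.gated for s in frame_steps(tr, AnalysisConfig(speed_gate_umh=g)))
                  for g in (0.0, 5.0, 10.0, 20.0, 40.0)]
        assert counts == sorted(counts, reverse=True)


class TestDirectionalChanges:
    def test_straight_line_zero(self):
        tr = _track([[0, 0], [10, 0], [20, 0], [30, 0]])
        assert np.allclose(directional_changes(tr), 0.0)

    def test_wrap_around(self):
        # directions 170 deg then -170 deg: the turn is +20, not -340
        p0 = np.array([0.0, 0.0])
        p1 = p0 + 20 * np.array([np.cos(np.deg2rad(170)), np.sin(np.deg2rad(170))])
        p2 = p1 + 20 * np.array([np.cos(np.deg2rad(-170)), np.sin(np.deg2rad(-170))])
        tr = _track([p0, p1, p2], hemisphere="right")
        assert directional_changes(tr) == pytest.approx([20.0])

    def test_hemisphere_flip_is_sign_involution(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.normal(0, 15, (12, 2)), axis=0)
        r = directional_changes(_track(pts, hemisphere="right"))
        l = directional_changes(_track(pts, hemisphere="left"))
        assert np.allclose(wrap_deg(-r), l)

    def test_too_few_gated_steps_empty(self):
        tr = _track([[0, 0], [0.1, 0], [0.2, 0]])  # sub-gate speeds
        assert directional_changes(tr).size == 0


class TestAnglesToRadial:
    def test_parallel_step_zero(self):
        tr = _track([[0, 0], [0, 20]])
        assert angles_to_radial(tr, RIGHT) == pytest.approx([0.0])

    def test_lateral_step_positive_90(self):
        # +x is lateral in the right hemisphere
        tr = _track([[0, 0], [20, 0]])
        assert angles_to_radial(tr, RIGHT) == pytest.approx([90.0])
        tr_l = _track([[0, 0], [-20, 0]], hemisphere="left")
        assert angles_to_radial(tr_l, LEFT) == pytest.approx([90.0])

    def test_matches_cross_dot_oracle(self):
        rng = np.random.default_rng(9)
        axis = np.array([0.3, 0.9539392014169457])
        axis /= np.linalg.norm(axis)
        frame = CorticalFrame(radial_axis=tuple(axis), upper_border_um=-100.0,
                              lower_border_um=0.0, hemisphere="right")
        pts = np.cumsum(rng.normal(0, 20, (15, 2)), axis=0)
        tr = _track(pts)
        got = angles_to_radial(tr, frame)
        cfg = AnalysisConfig()
        expected = []
        for i in range(len(pts) - 1):
            d = pts[i + 1] - pts[i]
            if np.linalg.norm(d) / 0.5 <= cfg.speed_gate_umh:
                continue
            cross = axis[0] * d[1] - axis[1] * d[0]
            dot = axis @ d
            ang = np.degrees(np.arctan2(cross, dot))
            expected.append(wrap_deg(-ang))  # lateral=+x in right hemisphere
        assert np.allclose(got, expected)

    def test_zero_radial_axis_rejected(self):
        with pytest.raises(ValueError):
            CorticalFrame(radial_axis=(0.0, 0.0), upper_border_um=-1, lower_border_um=0)


class TestPolarSummary:
    def test_closed_loop_flagged(self):
        tr = _track([[0, 0], [10, 0], [10, 10], [0, 0]])
        dist, direction = polar_summary(tr, RIGHT)
        assert dist == 0.0 and direction is None

    def test_straight_radial_run(self):
        tr = _track([[0, 0], [0, 50], [0, 100]])
        dist, direction = polar_summary(tr, RIGHT)
        assert dist == pytest.approx(100.0)
        assert direction == pytest.approx(0.0)

    def test_matches_endpoint_recomputation(self):
        rng = np.random.default_rng(4)
        tr = random_track(rng, n=30)
        dist, _ = polar_summary(tr, RIGHT)
        d = tr.xyz_um[-1, :2] - tr.xyz_um[0, :2]
        assert dist == pytest.approx(np.linalg.norm(d))


class TestMotileFilter:
    def test_oscillation_is_stationary(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0]] * 10)
        motile, stationary = motile_filter([_track(pts)])
        assert not motile and len(stationary) == 1

    def test_straight_run_is_motile(self):
        tr = _track([[0, 0], [12.5, 0], [25, 0]], dt=12.0)
        motile, stationary = motile_filter([tr])
        assert len(motile) == 1 and not stationary

    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(7)
        tracks = [random_track(rng, n=30, scale=rng.uniform(2, 30)) for _ in range(100)]
        cfg = AnalysisConfig()
        motile, stationary = motile_filter(tracks, cfg)
        got = {tr.track_id + str(i) for i, tr in enumerate(motile)}
        for i, tr in enumerate(tracks):
            mask = tr.t_h - tr.t_h[0] <= cfg.motility_window_h
            mx = max(np.linalg.norm(p - tr.xyz_um[0]) for p in tr.xyz_um[mask])
            assert (mx > cfg.motility_displacement_um) == (tr in motile)


class TestSpeedComparison:
    def test_identical_groups(self):
        rng = np.random.default_rng(5)
        tr = random_track(rng, n=100)
        steps = frame_steps(tr)
        rep = compare_speed_distributions(steps, steps)
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.p_two_sided == pytest.approx(1.0)

    def test_matches_textbook_welch_formula(self):
        a = np.array([31.0, 28.5, 35.2, 29.9, 33.1])
        b = np.array([12.0, 14.5, 11.2, 13.3, 12.8])
        steps_a = [type("S", (), {"speed_umh": v, "gated": True})() for v in a]
        steps_b = [type("S", (), {"speed_umh": v, "gated": True})() for v in b]
        rep = compare_speed_distributions(steps_a, steps_b)
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 4 + vb ** 2 / 4)
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(abs(t), df)
        assert rep.statistic == pytest.approx(t)
        assert rep.df == pytest.approx(df)
        assert rep.p_two_sided == pytest.approx(p)

    def test_small_group_rejected(self):
        s = [type("S", (), {"speed_umh": 20.0, "gated": True})()]
        with pytest.raises(ValueError):
            compare_speed_distributions(s, s)
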