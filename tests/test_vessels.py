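"""Vessel mask reconstruction, distances, exclusions and contact statistics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from astromigrate.config import AnalysisConfig, SimulationConfig
from astromigrate.datatypes import DistanceRecord, Track, VesselNetwork, VolumeStack
from astromigrate import synthetic
from astromigrate.vessels import (apply_edge_exclusion, association_fraction,
                                  build_vessel_mask, classify_track_contacts,
                                  contact_run_lengths, mask_from_occupancy,
                                  nearest_vessel_distance, off_on_ratio,
                                  on_vessel_persistence)


def _stack(arr, voxel=(1.0, 1.0, 1.0), name="vessels"):
    return VolumeStack(channels={name: np.asarray(arr, dtype=float)}, voxel_size_um=voxel)


class TestBuildMask:
    def test_all_zero_channel_gives_empty_mask(self, ana):
        mask = build_vessel_mask(_stack(np.zeros((8, 8, 8))), "vessels", 0.5, ana)
        assert mask.empty and not mask.occupancy.any()

    def test_missing_channel_and_bad_threshold(self, ana):
        stack = _stack(np.zeros((4, 4, 4)))
        with pytest.raises(KeyError):
            build_vessel_mask(stack, "nope", 0.5, ana)
        with pytest.raises(ValueError):
            build_vessel_mask(stack, "vessels", np.nan, ana)

    def test_surface_definition_exhaustive(self):
        rng = np.random.default_rng(2)
        occ = rng.random((12, 12, 12)) > 0.6
        mask = mask_from_occupancy(occ, (1.0, 1.0, 1.0))
        padded = np.pad(mask.occupancy, 1)
        for z, y, x in np.argwhere(mask.occupancy):
            nb = [padded[z + 1 + dz, y + 1 + dy, x + 1 + dx]
                  for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                     (0, -1, 0), (0, 0, 1), (0, 0, -1))]
            assert mask.surface[z, y, x] == (not all(nb))

    def test_skeleton_near_capsule_axis(self, ana):
        # straight capsule along x: skeleton stays within ~1 voxel of the axis
        net = VesselNetwork(np.array([[8.0, 16.0, 16.0, 56.0, 16.0, 16.0, 3.0]]))
        occ = synthetic.rasterize_capsules(net, (32, 32, 64), (1.0, 1.0, 1.0))
        mask = mask_from_occupancy(occ, (1.0, 1.0, 1.0))
        skel = np.argwhere(mask.skeleton)
        assert len(skel)
        centers = skel[:, ::-1] + 0.5  # x, y, z
        interior = (centers[:, 0] > 12) & (centers[:, 0] < 52)  # away from cap ends
        d = net.axis_distance(centers[interior])
        assert d.max() <= np.sqrt(3)

    def test_skeleton_and_surface_subsets(self, mask_small):
        assert not np.any(mask_small.skeleton & ~mask_small.occupancy)
        assert not np.any(mask_small.surface & ~mask_small.occupancy)


class TestNearestDistance:
    def test_empty_mask_is_error(self, ana):
        mask = build_vessel_mask(_stack(np.zeros((6, 6, 6))), "vessels", 0.5, ana)
        with pytest.raises(ValueError, match="empty"):
            nearest_vessel_distance([[3.0, 3.0, 3.0]], mask)

    def test_point_inside_occupancy_is_zero(self):
        occ = np.zeros((10, 10, 10), dtype=bool)
        occ[4:7, 4:7, 4:7] = True
        mask = mask_from_occupancy(occ, (1.0, 1.0, 1.0))
        (rec,) = nearest_vessel_distance([[5.5, 5.5, 5.5]], mask)
        assert rec.distance_um == 0.0

    def test_known_geometry(self):
        # 3-voxel cube block centred at (5.5, 5.5, 5.5): outer surface voxel
        # centre at x=6.5, so a centroid at x=14.5 on the same axis is 8 away
        occ = np.zeros((12, 12, 32), dtype=bool)
        occ[4:7, 4:7, 4:7] = True
        mask = mask_from_occupancy(occ, (1.0, 1.0, 1.0))
        (rec,) = nearest_vessel_distance([[14.5, 5.5, 5.5]], mask)
        assert rec.distance_um == pytest.approx(8.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_surface_scan(self, seed, ana):
        cfg = SimulationConfig(seed=seed, field_size_um=(64.0, 64.0, 64.0),
                               vessel_n_segments=int(np.random.default_rng(seed).integers(1, 6)))
        net = synthetic.generate_vessel_network(cfg)
        stack = synthetic.rasterize(net, [], 0, cfg)
        mask = build_vessel_mask(stack, "vessels", cfg.channel_amplitude / 2.0, ana)
        rng = np.random.default_rng(seed + 100)
        pts = rng.random((200, 3)) * 64.0
        recs = nearest_vessel_distance(pts, mask)
        surf = mask.surface_points_um
        brute = cdist(pts, surf).min(axis=1)
        inside = mask.occupancy[tuple(np.floor(pts[:, ::-1]).astype(int).clip(0, 63).T)]
        brute = np.where(inside, 0.0, brute)
        half_diag = 0.5 * np.sqrt(3.0)
        assert np.all(np.abs([r.distance_um for r in recs] - brute) <= half_diag)


class TestEdgeExclusion:
    def _rec(self, x, y, z):
        return DistanceRecord(cell_id="c", centroid_um=(x, y, z), distance_um=1.0)

    def test_z_limit(self, ana):
        (out,) = apply_edge_exclusion([self._rec(100, 100, 10.0)], (300, 300, 50), ana)
        assert not out.included and out.exclusion_reason == "z_limit"

    def test_xy_margin(self, ana):
        (out,) = apply_edge_exclusion([self._rec(19.0, 100, 25.0)], (300, 300, 50), ana)
        assert not out.included and out.exclusion_reason == "xy_margin"

    def test_interior_included(self, ana):
        (out,) = apply_edge_exclusion([self._rec(150, 150, 25.0)], (300, 300, 50), ana)
        assert out.included and out.exclusion_reason == "none"

    def test_matches_independent_box_test_and_conserves_records(self, ana):
        rng = np.random.default_rng(3)
        pts = rng.random((2000, 3)) * np.array([300.0, 300.0, 50.0])
        recs = [DistanceRecord(cell_id=f"c{i}", centroid_um=tuple(p), distance_um=0.0)
                for i, p in enumerate(pts)]
        out = apply_edge_exclusion(recs, (300.0, 300.0, 50.0), ana)
        assert len(out) == len(recs)  # no silent drops
        for r, p in zip(out, pts):
            x, y, z = p
            ok_z = ana.z_exclusion_um <= z <= 50.0 - ana.z_exclusion_um
            ok_xy = (ana.xy_margin_um <= x <= 300.0 - ana.xy_margin_um
                     and ana.xy_margin_um <= y <= 300.0 - ana.xy_margin_um)
            assert r.included == (ok_z and ok_xy)

    def test_out_of_bounds_centroid_rejected(self, ana):
        with pytest.raises(ValueError, match="outside field bounds"):
            apply_edge_exclusion([self._rec(-1.0, 10, 25)], (300, 300, 50), ana)


class TestAssociation:
    def test_all_zero_distances(self, ana):
        recs = [DistanceRecord(cell_id=str(i), centroid_um=(0, 0, 0), distance_um=0.0)
                for i in range(10)]
        frac, hist = association_fraction(recs, ana)
        assert frac == 1.0
        assert hist["counts"].sum() == 10

    def test_threshold_is_strict(self, ana):
        recs = [DistanceRecord(cell_id="a", centroid_um=(0, 0, 0), distance_um=5.0)]
        frac, _ = association_fraction(recs, ana)
        assert frac == 0.0  # exactly 5 um is not "< 5 um"

    def test_no_included_records_error(self, ana):
        recs = [DistanceRecord(cell_id="a", centroid_um=(0, 0, 0), distance_um=1.0,
                               included=False, exclusion_reason="z_limit")]
        with pytest.raises(ValueError):
            association_fraction(recs, ana)


class TestContacts:
    def test_inside_and_far_points(self, ana):
        occ = np.zeros((20, 20, 60), dtype=bool)
        occ[8:12, 8:12, 5:15] = True
        mask = mask_from_occupancy(occ, (1.0, 1.0, 1.0))
        tr = Track(track_id="t", hemisphere="right", t_h=[0.0, 1.0],
                   xyz_um=[[10.0, 10.0, 10.0], [55.0, 10.0, 10.0]])
        labels = classify_track_contacts(tr, mask, ana)
        assert labels.tolist() == [True, False]

    def test_vessel_guided_recovery(self, sim_small, network_small, mask_small, ana):
        tracks = synthetic.generate_tracks(sim_small, network_small,
                                           modes=("vessel_guided",))
        agree = []
        for tr in tracks:
            labels = classify_track_contacts(tr, mask_small, ana)
            if tr.contact.any():
                agree.append(labels[tr.contact].mean())
        # smoke-scale fixture (few short segments); the full-scale recovery
        # bound lives in the acceptance suite
        assert np.mean(agree) >= 0.85


class TestPersistence:
    def _track_with_labels(self, n, dt=0.5):
        t = np.arange(n) * dt
        xyz = np.column_stack([10.0 * t, np.zeros(n), np.zeros(n)])  # 10 um per 0.5h
        return Track(track_id="t", hemisphere="right", t_h=t, xyz_um=xyz)

    def test_short_run_not_selected(self, ana):
        tr = self._track_with_labels(20)
        labels = np.zeros(20, dtype=bool)
        labels[0:10] = True  # 4.5 h contiguous (9 intervals x 0.5 h)
        assert on_vessel_persistence(tr, labels, ana) is None

    def test_straight_run_distance(self, ana):
        # 6 h on vessel at 20 um/h -> selected; max distance over 24 h window
        n = 49
        t = np.arange(n) * 0.5
        xyz = np.column_stack([10.0 * t, np.zeros(n), np.zeros(n)])
        tr = Track(track_id="t", hemisphere="right", t_h=t, xyz_um=xyz)
        labels = np.zeros(n, dtype=bool)
        labels[0:13] = True  # 6 h contiguous
        assert on_vessel_persistence(tr, labels, ana) == pytest.approx(240.0)

    def test_matches_brute_force_max(self, ana):
        rng = np.random.default_rng(8)
        n = 30
        t = np.arange(n) * 0.5
        xyz = np.cumsum(rng.normal(0, 5, (n, 3)), axis=0)
        tr = Track(track_id="t", hemisphere="right", t_h=t, xyz_um=xyz)
        labels = np.ones(n, dtype=bool)
        got = on_vessel_persistence(tr, labels, ana)
        brute = max(np.linalg.norm(p - xyz[0]) for p in xyz)
        assert got == pytest.approx(brute)

    def test_run_segmentation(self):
        tr = self._track_with_labels(10)
        labels = np.array([1, 1, 0, 1, 1, 1, 0, 0, 1, 1], dtype=bool)
        runs = contact_run_lengths(tr, labels)
        assert [(a, b) for a, b, _ in runs] == [(0, 1), (3, 5), (8, 9)]
        assert runs[1][2] == pytest.approx(1.0)


class TestOffOnRatio:
    def _tr(self, duration_h, on_fraction, tid="t"):
        n = max(int(duration_h / 0.5) + 1, 2)
        t = np.arange(n) * 0.5
        xyz = np.zeros((n, 3)) + np.arange(n)[:, None]
        labels = np.zeros(n, dtype=bool)
        labels[: int(round(on_fraction * n))] = True
        return (Track(track_id=tid, hemisphere="right", t_h=t, xyz_um=xyz), labels)

    def test_balanced_field(self, ana):
        pairs = [self._tr(24, 1.0, f"on{i}") for i in range(4)]
        pairs += [self._tr(24, 0.0, f"off{i}") for i in range(4)]
        (res,) = off_on_ratio({"f": pairs}, ana)
        assert res.ratio == 1.0 and res.n_on == 4 and res.n_off == 4

    def test_short_track_excluded(self, ana):
        (res,) = off_on_ratio({"f": [self._tr(9.0, 1.0)]}, ana)
        assert res.n_excluded == 1 and res.n_on == 0 and res.ratio is None

    def test_constructed_composition_exact(self, ana):
        pairs = ([self._tr(24, 0.9, f"a{i}") for i in range(3)]      # majority on
                 + [self._tr(24, 0.2, f"b{i}") for i in range(6)]    # majority off
                 + [self._tr(8, 1.0, "short")])                      # excluded
        (res,) = off_on_ratio({"f": pairs}, ana)
        assert (res.n_on, res.n_off, res.n_excluded) == (3, 6, 1)
        assert res.ratio == pytest.approx(2.0)
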