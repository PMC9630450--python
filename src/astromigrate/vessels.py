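"""Vessel proximity pipeline.

Reconstructs a voxelized vessel mask from the endothelial channel
(threshold, small-object removal, 3D medial-axis skeleton, 6-connectivity
surface), measures centre-to-surface nearest distances from cell centroids,
applies the imaging-edge exclusions (15 um at either Z face, 20 um at the
XY borders), and derives the association statistics: the <5 um association
fraction with its histogram, per-frame on/off-vessel track labels, the
>=5 h on-vessel persistence selection with maximum travel distance, and the
per-field off/on ratio for tube co-culture fields.

Distances are anisotropy-aware: all geometry is computed in physical um
using the per-axis voxel size.  Centre-to-surface distances are taken to
surface-voxel centres (no sub-voxel interpolation); the natural tolerance
on such distances is half the voxel diagonal.  Contact classification
instead measures the distance from a point to the occupied voxel *region*
(centre distance minus half the voxel diagonal, floored at zero), so a
point touching the rasterized vessel gets distance 0 and the default
``contact_tolerance_um = 0`` means overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import remove_small_objects, skeletonize

from .config import AnalysisConfig
from .datatypes import DistanceRecord, Track, VesselMask, VolumeStack

__all__ = [
    "build_vessel_mask",
    "mask_from_occupancy",
    "nearest_vessel_distance",
    "apply_edge_exclusion",
    "association_fraction",
    "classify_track_contacts",
    "contact_run_lengths",
    "on_vessel_persistence",
    "off_on_ratio",
]

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def mask_from_occupancy(occupancy: np.ndarray,
                        voxel_size_um: Tuple[float, float, float]) -> VesselMask:
    """Build skeleton and surface from a boolean occupancy array.

    The surface is the set of occupied voxels with at least one empty
    6-neighbour; voxels on the array boundary count as surface (the volume
    edge is background).  The skeleton is the 3D medial axis; it is retained
    for QC and path projection, distances are always measured to the surface.
    """
    occupancy = np.ascontiguousarray(occupancy, dtype=bool)
    empty = not occupancy.any()
    if empty:
        zeros = np.zeros_like(occupancy)
        return VesselMask(occupancy=occupancy, voxel_size_um=tuple(voxel_size_um),
                          skeleton=zeros, surface=zeros.copy(), empty=True)
    skeleton = skeletonize(occupancy)
    # 3D thinning can annihilate tubes of even symmetric diameter; for any
    # component left without a single skeleton voxel, fall back to the ridge
    # of the interior distance transform (the discrete medial locus)
    labels, n = ndimage.label(occupancy, structure=np.ones((3, 3, 3), bool))
    missing = set(range(1, n + 1)) - set(np.unique(labels[skeleton]))
    if missing:
        edt_in = ndimage.distance_transform_edt(occupancy, sampling=voxel_size_um)
        ridge = occupancy & (edt_in >= ndimage.maximum_filter(edt_in, size=3))
        for m in missing:
            skeleton |= ridge & (labels == m)
    interior = ndimage.binary_erosion(occupancy, structure=_SIX_CONN, border_value=0)
    surface = occupancy & ~interior
    return VesselMask(occupancy=occupancy, voxel_size_um=tuple(voxel_size_um),
                      skeleton=skeleton, surface=surface, empty=False)


def build_vessel_mask(stack: VolumeStack, channel: str, threshold: float,
                      config: Optional[AnalysisConfig] = None) -> VesselMask:
    """Threshold a vessel channel and reconstruct the voxel mask.

    Voxels with intensity >= ``threshold`` are foreground; connected
    components smaller than ``config.min_component_voxels`` are removed as
    noise before skeletonization.  An all-background result is a valid empty
    mask with ``empty=True``.
    """
    config = config or AnalysisConfig()
    if channel not in stack.channels:
        raise KeyError(f"channel {channel!r} not in stack ({sorted(stack.channels)})")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    occupancy = stack.channels[channel] >= threshold
    if config.min_component_voxels > 1:
        # drop connected components below the minimum size
        occupancy = remove_small_objects(occupancy, max_size=config.min_component_voxels - 1)
    return mask_from_occupancy(occupancy, stack.voxel_size_um)


def _surface_tree(mask: VesselMask) -> cKDTree:
    pts = mask.surface_points_um
    if pts.shape[0] == 0:
        raise ValueError("vessel mask is empty: distances are undefined")
    return cKDTree(pts)


def nearest_vessel_distance(centroids: Sequence[Sequence[float]], mask: VesselMask,
                            cell_ids: Optional[Sequence[str]] = None) -> List[DistanceRecord]:
    """Centre-to-surface distance from each centroid to the nearest vessel.

    Distances are Euclidean in physical um to the nearest *surface-voxel
    centre*; centroids falling inside the occupancy get distance 0.  An
    empty mask is an explicit error.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if mask.empty or not mask.occupancy.any():
        raise ValueError("vessel mask is empty: distances are undefined")
    tree = _surface_tree(mask)
    d, _ = tree.query(centroids)
    # interior points are distance 0 by definition
    vz, vy, vx = mask.voxel_size_um
    zyx = np.floor(centroids[:, ::-1] / np.array([vz, vy, vx])).astype(int)
    shape = np.array(mask.occupancy.shape)
    inside = np.all((zyx >= 0) & (zyx < shape), axis=1)
    occ = np.zeros(centroids.shape[0], dtype=bool)
    occ[inside] = mask.occupancy[tuple(zyx[inside].T)]
    d = np.where(occ, 0.0, d)
    ids = list(cell_ids) if cell_ids is not None else [f"c{i:05d}" for i in range(len(d))]
    return [DistanceRecord(cell_id=i, centroid_um=tuple(c), distance_um=float(v))
            for i, c, v in zip(ids, centroids, d)]


def apply_edge_exclusion(records: Sequence[DistanceRecord],
                         field_bounds_um: Tuple[float, float, float],
                         config: Optional[AnalysisConfig] = None) -> List[DistanceRecord]:
    """Flag records near the imaged-volume edges; nothing is deleted.

    A centroid within ``z_exclusion_um`` of either Z face is excluded with
    reason ``z_limit`` (checked first); one within ``xy_margin_um`` of any
    XY border with reason ``xy_margin``.  Exclusion exists because a closer
    vessel could lie just outside the imaged space.
    """
    config = config or AnalysisConfig()
    fx, fy, fz = field_bounds_um
    out = []
    for r in records:
        x, y, z = r.centroid_um
        if not (0.0 <= x <= fx and 0.0 <= y <= fy and 0.0 <= z <= fz):
            raise ValueError(f"centroid {r.centroid_um} outside field bounds {field_bounds_um}")
        if z < config.z_exclusion_um or z > fz - config.z_exclusion_um:
            reason = "z_limit"
        elif (x < config.xy_margin_um or x > fx - config.xy_margin_um
              or y < config.xy_margin_um or y > fy - config.xy_margin_um):
            reason = "xy_margin"
        else:
            reason = "none"
        out.append(DistanceRecord(cell_id=r.cell_id, centroid_um=r.centroid_um,
                                  distance_um=r.distance_um,
                                  included=(reason == "none"), exclusion_reason=reason))
    return out


def association_fraction(records: Sequence[DistanceRecord],
                         config: Optional[AnalysisConfig] = None,
                         ) -> Tuple[float, Dict[str, np.ndarray]]:
    """Fraction of included cells closer than the association threshold.

    Also returns the distance histogram (bin width
    ``config.histogram_bin_um``, default 2.5 um) for violin/peak inspection.
    """
    config = config or AnalysisConfig()
    d = np.array([r.distance_um for r in records if r.included])
    if d.size == 0:
        raise ValueError("no included records: association fraction undefined")
    frac = float(np.mean(d < config.association_threshold_um))
    top = max(d.max(), config.association_threshold_um)
    edges = np.arange(0.0, top + config.histogram_bin_um, config.histogram_bin_um)
    counts, edges = np.histogram(d, bins=edges)
    return frac, {"counts": counts, "edges": edges}


def _mask_edt(mask: VesselMask) -> np.ndarray:
    """Anisotropic EDT of the background, cached on the mask instance."""
    edt = getattr(mask, "_edt", None)
    if edt is None:
        edt = ndimage.distance_transform_edt(~mask.occupancy, sampling=mask.voxel_size_um)
        mask._edt = edt  # lazily cached; masks are treated as immutable after build
    return edt


def _point_region_distance(points_xyz: np.ndarray, mask: VesselMask) -> np.ndarray:
    """Distance from points to the occupied voxel region (0 when touching).

    The anisotropic EDT gives the distance field to the nearest occupied
    voxel centre; it is sampled at the exact point position by trilinear
    interpolation, and half the voxel diagonal is subtracted (clamping at
    zero) to account for the extent of the occupied voxel, so points on the
    rasterized vessel surface come out at distance 0.
    """
    vz, vy, vx = mask.voxel_size_um
    if mask.occupancy.all():
        return np.zeros(np.atleast_2d(points_xyz).shape[0])
    edt = _mask_edt(mask)
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
    coords = (pts[:, ::-1] / np.array([vz, vy, vx])) - 0.5  # voxel-centre grid coords
    d = ndimage.map_coordinates(edt, coords.T, order=1, mode="nearest")
    half_diag = 0.5 * np.sqrt(vz**2 + vy**2 + vx**2)
    return np.maximum(d - half_diag, 0.0)


def classify_track_contacts(track: Track, mask: VesselMask,
                            config: Optional[AnalysisConfig] = None) -> np.ndarray:
    """Per-sample on/off-vessel labels for one track against a static mask.

    A sample is "on" iff its distance to the occupied vessel region is at
    most ``contact_tolerance_um`` (default 0: inside or touching the
    occupancy) — the analog of fusing the cell and vessel channels and
    keeping overlapping signals.
    """
    config = config or AnalysisConfig()
    if mask.empty:
        return np.zeros(track.n_samples, dtype=bool)
    d = _point_region_distance(track.xyz_um, mask)
    return d <= config.contact_tolerance_um


def contact_run_lengths(track: Track, labels: np.ndarray) -> List[Tuple[int, int, float]]:
    """Contiguous on-vessel runs as (start_idx, end_idx_inclusive, duration_h)."""
    runs = []
    labels = np.asarray(labels, dtype=bool)
    i = 0
    while i < labels.size:
        if labels[i]:
            j = i
            while j + 1 < labels.size and labels[j + 1]:
                j += 1
            runs.append((i, j, float(track.t_h[j] - track.t_h[i])))
            i = j + 1
        else:
            i += 1
    return runs


def on_vessel_persistence(track: Track, labels: np.ndarray,
                          config: Optional[AnalysisConfig] = None) -> Optional[float]:
    """Maximum travel distance of persistently vessel-bound cells.

    A track qualifies iff some contiguous on-vessel run lasts at least
    ``min_on_vessel_h`` (default 5 h); for qualifying tracks the maximum
    Euclidean distance from the start position over the whole observation is
    returned, otherwise ``None`` (the track is not selected).
    """
    config = config or AnalysisConfig()
    runs = contact_run_lengths(track, labels)
    if not any(dur >= config.min_on_vessel_h for _, _, dur in runs):
        return None
    d = np.linalg.norm(track.xyz_um - track.xyz_um[0], axis=1)
    return float(d.max())


@dataclass
class FieldRatio:
    """Off/on migration ratio of one objective field."""

    field_id: str
    n_on: int
    n_off: int
    n_excluded: int
    ratio: Optional[float]  # None when no on-cells (flagged, not infinity)


def off_on_ratio(fields: Dict[str, Sequence[Tuple[Track, np.ndarray]]],
                 config: Optional[AnalysisConfig] = None) -> List[FieldRatio]:
    """Per-field ratio of off-vessel to on-vessel migrating cells.

    Only tracks traceable for at least ``traceability_min_h`` (default 10 h)
    are counted.  A whole track is called "on" when the majority of its
    labelled frames are on-vessel (majority rule).  Fields without any
    on-cell get ``ratio=None`` rather than infinity.
    """
    config = config or AnalysisConfig()
    out = []
    for field_id, pairs in fields.items():
        n_on = n_off = n_excluded = 0
        for track, labels in pairs:
            if track.duration_h < config.traceability_min_h:
                n_excluded += 1
                continue
            labels = np.asarray(labels, dtype=bool)
            if labels.mean() > 0.5:
                n_on += 1
            else:
                n_off += 1
        ratio = (n_off / n_on) if n_on > 0 else None
        out.append(FieldRatio(field_id=field_id, n_on=n_on, n_off=n_off,
                              n_excluded=n_excluded, ratio=ratio))
    return out
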