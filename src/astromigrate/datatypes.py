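"""Shared domain containers.

All coordinates are physical micrometres in a right-handed frame with +y
pointing radially toward the pial surface; intensity arrays are indexed
(Z, Y, X).  Physical <-> index mapping places the centre of voxel ``i`` at
``(i + 0.5) * voxel_size`` along each axis, so a round trip through
:func:`VolumeStack.physical_to_index` / ``index_to_physical`` moves a point
by at most half a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "VesselNetwork",
    "Track",
    "VolumeStack",
    "VesselMask",
    "DistanceRecord",
    "CorticalFrame",
    "CellDetection",
    "FrameStep",
]


@dataclass(frozen=True, eq=False)
class VesselNetwork:
    """Tubular vessel geometry as straight capsule segments.

    ``segments`` is an (n, 7) float array: x0, y0, z0, x1, y1, z1, radius_um.
    """

    segments: np.ndarray

    def __post_init__(self) -> None:
        seg = np.asarray(self.segments, dtype=float).reshape(-1, 7)
        if seg.size and np.any(seg[:, 6] <= 0):
            raise ValueError("vessel segment radii must be strictly positive")
        object.__setattr__(self, "segments", seg)

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def p0(self) -> np.ndarray:
        return self.segments[:, 0:3]

    @property
    def p1(self) -> np.ndarray:
        return self.segments[:, 3:6]

    @property
    def radii(self) -> np.ndarray:
        return self.segments[:, 6]

    def axis_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest segment *axis*."""
        return _points_to_segments(points, self.p0, self.p1).min(axis=1)

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed-free distance to the nearest capsule surface (0 inside)."""
        d = _points_to_segments(points, self.p0, self.p1) - self.radii[None, :]
        return np.maximum(d.min(axis=1), 0.0)

    def capsule_volume_um3(self) -> float:
        """Sum of isolated capsule volumes (overlaps counted twice)."""
        if self.n_segments == 0:
            return 0.0
        length = np.linalg.norm(self.p1 - self.p0, axis=1)
        r = self.radii
        return float(np.sum(np.pi * r**2 * length + 4.0 / 3.0 * np.pi * r**3))

    def volume_fraction(self, field_size_um: Sequence[float], n_samples: int = 200_000,
                        seed: int = 0, dilate_um: float = 0.0) -> float:
        """Monte-Carlo union-of-capsules volume fraction of the field.

        The estimate handles capsule overlaps exactly (a sampled point is
        counted once no matter how many capsules cover it).  ``dilate_um``
        grows every capsule radius, which gives the volume fraction of the
        d-dilated vessel set used by the association null model.
        """
        fx, fy, fz = field_size_um
        if self.n_segments == 0:
            return 0.0
        rng = np.random.default_rng(seed)
        pts = rng.random((n_samples, 3)) * np.array([fx, fy, fz])
        d = _points_to_segments(pts, self.p0, self.p1)
        inside = np.any(d <= (self.radii + dilate_um)[None, :], axis=1)
        return float(inside.mean())


def _points_to_segments(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """(n_points, n_segments) matrix of point-to-segment distances."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = p1 - p0  # (m, 3)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    w = points[:, None, :] - p0[None, :, :]  # (n, m, 3)
    t = np.clip(np.einsum("nmj,mj->nm", w, d) / seg_len2, 0.0, 1.0)
    closest = p0[None, :, :] + t[:, :, None] * d[None, :, :]
    return np.linalg.norm(points[:, None, :] - closest, axis=2)


@dataclass(eq=False)
class Track:
    """One cell's time-stamped positions in physical units.

    ``t_h`` is strictly increasing (hours); ``xyz_um`` is (n, 3) in x, y, z
    order.  ``contact`` is the per-sample on-vessel ground truth emitted by
    the simulator and ``true_mode`` its generating migration class; both are
    absent for measured data.
    """

    track_id: str
    hemisphere: str
    t_h: np.ndarray
    xyz_um: np.ndarray
    true_mode: Optional[str] = None
    contact: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.xyz_um = np.asarray(self.xyz_um, dtype=float).reshape(-1, 3)
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.t_h.ndim != 1 or self.t_h.size != self.xyz_um.shape[0]:
            raise ValueError("t_h and xyz_um must have matching lengths")
        if self.t_h.size < 2:
            raise ValueError("a track needs at least 2 samples")
        dt = np.diff(self.t_h)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"timestamps must strictly increase (violation at sample {bad})")
        if self.contact is not None:
            self.contact = np.asarray(self.contact, dtype=bool)
            if self.contact.shape != self.t_h.shape:
                raise ValueError("contact flags must match the number of samples")

    @property
    def n_samples(self) -> int:
        return self.t_h.size

    @property
    def duration_h(self) -> float:
        return float(self.t_h[-1] - self.t_h[0])


@dataclass(eq=False)
class VolumeStack:
    """Multi-channel 3D intensity volume with per-axis voxel size.

    ``channels`` maps channel name -> float array indexed (Z, Y, X);
    ``voxel_size_um`` is (z, y, x).
    """

    channels: Dict[str, np.ndarray]
    voxel_size_um: Tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size_um
        return vz * vy * vx

    def physical_to_index(self, xyz_um: np.ndarray) -> np.ndarray:
        """Map physical (x, y, z) um points to integer (z, y, x) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz_um, dtype=float))
        vz, vy, vx = self.voxel_size_um
        zyx = np.floor(xyz[:, ::-1] / np.array([vz, vy, vx])).astype(int)
        return np.clip(zyx, 0, np.array(self.shape) - 1)

    def index_to_physical(self, zyx: np.ndarray) -> np.ndarray:
        """Map (z, y, x) voxel indices to the physical (x, y, z) voxel centres."""
        zyx = np.atleast_2d(np.asarray(zyx, dtype=float))
        centers = (zyx + 0.5) * np.array(self.voxel_size_um)
        return centers[:, ::-1]


@dataclass(eq=False)
class VesselMask:
    """Voxelized vessel reconstruction: occupancy, medial-axis skeleton, surface."""

    occupancy: np.ndarray
    voxel_size_um: Tuple[float, float, float]
    skeleton: np.ndarray
    surface: np.ndarray
    empty: bool = False

    def __post_init__(self) -> None:
        for name in ("skeleton", "surface"):
            arr = getattr(self, name)
            if arr.shape != self.occupancy.shape:
                raise ValueError(f"{name} must match occupancy shape")
            if np.any(arr & ~self.occupancy):
                raise ValueError(f"{name} must be a subset of the occupancy")

    @property
    def surface_points_um(self) -> np.ndarray:
        """Physical (x, y, z) centres of the surface voxels."""
        zyx = np.argwhere(self.surface).astype(float)
        centers = (zyx + 0.5) * np.array(self.voxel_size_um)
        return centers[:, ::-1]


@dataclass
class DistanceRecord:
    """One cell's centre-to-surface vessel distance and its inclusion status."""

    cell_id: str
    centroid_um: Tuple[float, float, float]
    distance_um: float
    included: bool = True
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise ValueError("distance_um must be non-negative")
        if self.included != (self.exclusion_reason == "none"):
            raise ValueError("included flag inconsistent with exclusion_reason")


@dataclass(frozen=True)
class CorticalFrame:
    """Geometric reference for depth statistics.

    ``radial_axis`` is the in-plane unit vector pointing toward the pial
    surface.  Border positions are coordinates along the *depth* direction
    (the negated radial axis), so the pial-side border satisfies
    ``upper_border_um < lower_border_um`` and depth grows away from the
    surface.
    """

    radial_axis: Tuple[float, float]
    upper_border_um: float
    lower_border_um: float
    hemisphere: str = "right"

    def __post_init__(self) -> None:
        ax = np.asarray(self.radial_axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("radial axis must be non-zero")
        object.__setattr__(self, "radial_axis", tuple(ax / n))
        if not self.upper_border_um < self.lower_border_um:
            raise ValueError("upper border must lie above (before) the lower border")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")

    def depth_coordinate(self, xy_um: np.ndarray) -> np.ndarray:
        """Projection of in-plane points onto the depth (anti-radial) axis."""
        xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
        ax = np.asarray(self.radial_axis)
        return -(xy @ ax)


@dataclass
class CellDetection:
    """A detected double-positive cell."""

    cell_id: str
    centroid_um: Tuple[float, float, float]
    volume_um3: float
    mean_intensity: Dict[str, float] = field(default_factory=dict)


@dataclass
class FrameStep:
    """One frame-to-frame displacement of a track."""

    track_id: str
    t_mid: float
    displacement_um: float
    speed_umh: float
    direction_deg: Optional[float]  # in-plane, CCW from +x; None when stationary
    gated: bool
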