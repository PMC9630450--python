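"""Synthetic slice-imaging generator.

The generator emulates the inputs the analysis modules expect from a
time-lapse slice-culture experiment on the developing cortex:

* a radially biased 3D vessel network (the endothelial channel of a
  *Flt1-DsRed*-like slice), rasterizable to a voxel mask;
* trajectories of the three migration classes — *erratic* (fast, weakly
  persistent random walk with a net surface-ward drift), *radial* (slower,
  strongly directed toward the pial surface) and *vessel-guided*
  (constrained to the capsule surfaces of the network, with stochastic
  attach/detach events);
* uniform nuclei point clouds standing in for the DAPI-stained reference
  population;
* two-channel intensity volumes (vessels as capsules, cells as Gaussian
  blobs) with additive Gaussian noise.

Every generator is a pure function of its configuration: the same
``SimulationConfig`` (including its ``seed``) yields byte-identical output.
Randomness is split per product via ``numpy.random.SeedSequence`` spawn
keys, so e.g. the vessel network does not change when the number of cells
does.

Coordinates are physical micrometres, +y radial toward the pial surface;
rasterized arrays are indexed (Z, Y, X).
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .config import SimulationConfig
from .datatypes import Track, VesselNetwork, VolumeStack, _points_to_segments

__all__ = [
    "generate_vessel_network",
    "generate_tracks",
    "generate_nuclei",
    "generate_cell_positions",
    "generate_depth_cohort",
    "rasterize",
    "blob_sigma_um",
]

_RADIAL = np.array([0.0, 1.0, 0.0])
_CONE_DEG = 30.0  # a segment is "radial" when its axis is within this of +y


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Deterministic per-stream generator derived from the config seed."""
    key = int.from_bytes(stream.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(key,)))


def _sample_cap_direction(rng: np.random.Generator, cos_min: float) -> np.ndarray:
    """Uniform direction on the spherical cap around +y with cos(angle) >= cos_min."""
    c = rng.uniform(cos_min, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(1.0 - c * c)
    # cap is centred on +y: y carries the cosine
    return np.array([s * np.cos(phi), c, s * np.sin(phi)])


def _sample_offaxis_direction(rng: np.random.Generator, cos_min: float) -> np.ndarray:
    """Uniform direction whose *axial* angle to +y exceeds the cone angle."""
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n == 0:
            continue
        v /= n
        if abs(v[1]) < cos_min:  # axial angle: fold the two hemispheres together
            return v


def generate_vessel_network(config: SimulationConfig) -> VesselNetwork:
    """Generate a radially biased capsule network inside the field.

    Each segment is oriented within 30 degrees of the radial (+y) axis with
    probability ``vessel_radial_bias`` and strictly outside that cone
    otherwise, so the realized radial fraction is Binomial(n, bias).
    Endpoints are clamped to the field bounds; segments that cannot fit are
    re-drawn.
    """
    fx, fy, fz = config.field_size_um
    rng = _rng(config, "vessels")
    cos_min = np.cos(np.deg2rad(_CONE_DEG))
    # keep endpoints one radius inside the field so the whole capsule
    # surface (where guided cells sit) stays within bounds
    r = config.vessel_radius_um
    lo = np.full(3, r)
    hi = np.array([fx - r, fy - r, fz - r])
    length_range = (0.25 * min(fx, fy), 0.6 * min(fx, fy))

    segments = []
    while len(segments) < config.vessel_n_segments:
        center = rng.random(3) * hi
        if rng.random() < config.vessel_radial_bias:
            d = _sample_cap_direction(rng, cos_min)
        else:
            d = _sample_offaxis_direction(rng, cos_min)
        length = rng.uniform(*length_range)
        # clamp the parameter range so both endpoints stay inside the field
        t_lo, t_hi = -length / 2.0, length / 2.0
        for axis in range(3):
            if d[axis] > 1e-12:
                t_lo = max(t_lo, (lo[axis] - center[axis]) / d[axis])
                t_hi = min(t_hi, (hi[axis] - center[axis]) / d[axis])
            elif d[axis] < -1e-12:
                t_lo = max(t_lo, (hi[axis] - center[axis]) / d[axis])
                t_hi = min(t_hi, (lo[axis] - center[axis]) / d[axis])
        if t_hi - t_lo < 5.0:  # too short after clamping: re-draw
            continue
        p0 = center + t_lo * d
        p1 = center + t_hi * d
        segments.append(np.concatenate([p0, p1, [config.vessel_radius_um]]))
    if not segments:
        return VesselNetwork(np.empty((0, 7)))
    return VesselNetwork(np.array(segments))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) for a lognormal with arithmetic mean/sd."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _reflect(p: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect a point into [0, hi] per axis (preserves per-axis step length)."""
    p = np.abs(p)
    over = p > hi
    p[over] = 2 * hi[over] - p[over]
    return np.clip(p, 0.0, hi)


def _walk_track(rng, config: SimulationConfig, start: np.ndarray, *,
                speed_mean: float, speed_sd: float, turn_sd_deg: float,
                drift_umh: float, z_jitter_um: float = 0.5) -> np.ndarray:
    """2D-heading random walk with lognormal speeds and wrapped-normal turns."""
    hi = np.array(config.field_size_um, dtype=float)
    dt = config.frame_interval_h
    n = config.n_frames
    mu, sigma = _lognormal_params(speed_mean, speed_sd)
    heading = rng.uniform(0.0, 2.0 * np.pi)
    pos = start.copy()
    out = np.empty((n, 3))
    out[0] = pos
    for i in range(1, n):
        heading += np.deg2rad(rng.normal(0.0, turn_sd_deg)) if turn_sd_deg > 0 else 0.0
        speed = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else speed_mean
        step = speed * dt * np.array([np.cos(heading), np.sin(heading), 0.0])
        step[1] += drift_umh * dt
        step[2] += rng.normal(0.0, z_jitter_um) if z_jitter_um > 0 else 0.0
        pos = _reflect(pos + step, hi)
        out[i] = pos
    return out


def _radial_track(rng, config: SimulationConfig, start: np.ndarray) -> np.ndarray:
    """Surface-ward directed walk: heading re-drawn around +y every frame."""
    hi = np.array(config.field_size_um, dtype=float)
    dt = config.frame_interval_h
    n = config.n_frames
    mu, sigma = _lognormal_params(config.radial_speed_mean_umh, config.radial_speed_sd)
    pos = start.copy()
    out = np.empty((n, 3))
    out[0] = pos
    base = np.pi / 2.0  # +y
    for i in range(1, n):
        ang = base + (np.deg2rad(rng.normal(0.0, config.radial_turn_sd_deg))
                      if config.radial_turn_sd_deg > 0 else 0.0)
        speed = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else config.radial_speed_mean_umh
        step = speed * dt * np.array([np.cos(ang), np.sin(ang), 0.0])
        pos = _reflect(pos + step, hi)
        out[i] = pos
    return out


def _vessel_guided_track(rng, config: SimulationConfig, vessels: VesselNetwork,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Agent alternating between on-vessel crawling and free wandering.

    While attached the agent sits exactly one radius from its segment axis
    (on the abluminal surface) and crawls along the axis at
    ``vessel_guided_speed_umh``; it detaches stochastically or on reaching a
    segment end.  While detached it moves as an erratic walker and re-attaches
    with ``attach_prob_per_frame`` whenever it comes within
    ``capture_radius_um`` of a capsule surface.  Returns positions and the
    per-sample contact (attached) flags.
    """
    hi = np.array(config.field_size_um, dtype=float)
    dt = config.frame_interval_h
    n = config.n_frames
    p0, p1, radii = vessels.p0, vessels.p1, vessels.radii
    axes = p1 - p0
    lengths = np.linalg.norm(axes, axis=1)
    units = axes / lengths[:, None]

    def surface_point(seg: int, s: float, azimuth: float) -> np.ndarray:
        u = units[seg]
        # orthonormal frame around the axis
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(u, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        normal = np.cos(azimuth) * e1 + np.sin(azimuth) * e2
        return p0[seg] + s * u + radii[seg] * normal

    # start attached at a random point of a random segment
    seg = int(rng.integers(vessels.n_segments))
    s = float(rng.uniform(0.0, lengths[seg]))
    azimuth = float(rng.uniform(0.0, 2.0 * np.pi))
    sign = np.sign(units[seg][1]) or (1.0 if rng.random() < 0.5 else -1.0)
    attached = True
    pos = surface_point(seg, s, azimuth)

    mu, sigma = _lognormal_params(config.erratic_speed_mean_umh, config.erratic_speed_sd)
    heading = rng.uniform(0.0, 2.0 * np.pi)

    out = np.empty((n, 3))
    contact = np.zeros(n, dtype=bool)
    out[0], contact[0] = pos, attached
    for i in range(1, n):
        if attached and rng.random() < config.detach_prob_per_frame:
            attached = False
        if attached:
            s += sign * config.vessel_guided_speed_umh * dt
            if s < 0.0 or s > lengths[seg]:
                s = float(np.clip(s, 0.0, lengths[seg]))
                pos = surface_point(seg, s, azimuth)
                attached = False  # ran off the segment end
            else:
                pos = surface_point(seg, s, azimuth)
        else:
            heading += np.deg2rad(rng.normal(0.0, config.erratic_turn_sd_deg))
            speed = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else config.erratic_speed_mean_umh
            step = speed * dt * np.array([np.cos(heading), np.sin(heading), 0.0])
            step[2] += rng.normal(0.0, 0.5)
            pos = _reflect(pos + step, hi)
            d_axis = _points_to_segments(pos[None, :], p0, p1)[0]
            near = d_axis - radii  # distance to each capsule surface
            j = int(np.argmin(near))
            if near[j] <= config.capture_radius_um and rng.random() < config.attach_prob_per_frame:
                attached = True
                seg = j
                u = units[seg]
                w = pos - p0[seg]
                s = float(np.clip(w @ u, 0.0, lengths[seg]))
                radial_vec = w - (w @ u) * u
                nrm = np.linalg.norm(radial_vec)
                if nrm > 1e-9:
                    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
                    e1 = np.cross(u, ref)
                    e1 /= np.linalg.norm(e1)
                    e2 = np.cross(u, e1)
                    azimuth = float(np.arctan2(radial_vec @ e2, radial_vec @ e1))
                else:
                    azimuth = float(rng.uniform(0.0, 2.0 * np.pi))
                sign = np.sign(u[1]) or (1.0 if rng.random() < 0.5 else -1.0)
                pos = surface_point(seg, s, azimuth)
        out[i], contact[i] = pos, attached
    return out, contact


def generate_tracks(config: SimulationConfig, vessels: Optional[VesselNetwork] = None,
                    modes: Sequence[str] = ("erratic", "radial", "vessel_guided"),
                    ) -> List[Track]:
    """Generate ``n_cells_per_mode`` tracks per requested migration mode.

    Vessel-guided tracks require a non-empty ``vessels`` network; requesting
    them without one is an error.  Hemispheres alternate deterministically so
    both sign conventions are exercised.
    """
    for m in modes:
        if m not in ("erratic", "radial", "vessel_guided"):
            raise ValueError(f"unknown migration mode {m!r}")
    if "vessel_guided" in modes and (vessels is None or vessels.n_segments == 0):
        raise ValueError("vessel-guided tracks require a non-empty vessel network")

    fx, fy, fz = config.field_size_um
    t = np.arange(config.n_frames) * config.frame_interval_h
    tracks: List[Track] = []
    prefix = {"erratic": "e", "radial": "r", "vessel_guided": "v"}
    for mode in modes:
        rng = _rng(config, f"tracks-{mode}")
        for i in range(config.n_cells_per_mode):
            margin = 5.0
            start = np.array([
                rng.uniform(margin, fx - margin),
                rng.uniform(margin, 0.6 * fy),  # start deep so radial runs have room
                rng.uniform(margin, fz - margin),
            ])
            contact = None
            if mode == "erratic":
                xyz = _walk_track(rng, config, start,
                                  speed_mean=config.erratic_speed_mean_umh,
                                  speed_sd=config.erratic_speed_sd,
                                  turn_sd_deg=config.erratic_turn_sd_deg,
                                  drift_umh=config.erratic_drift_umh)
            elif mode == "radial":
                xyz = _radial_track(rng, config, start)
            else:
                xyz, contact = _vessel_guided_track(rng, config, vessels)
            tracks.append(Track(
                track_id=f"{prefix[mode]}{i:03d}",
                hemisphere="right" if i % 2 == 0 else "left",
                t_h=t.copy(),
                xyz_um=xyz,
                true_mode=mode,
                contact=contact,
            ))
    return tracks


def generate_nuclei(config: SimulationConfig, n: int) -> np.ndarray:
    """Uniform (x, y, z) nuclei positions over the field — the DAPI reference."""
    if n == 0:
        return np.empty((0, 3))
    rng = _rng(config, "nuclei")
    return rng.random((n, 3)) * np.array(config.field_size_um)


def generate_cell_positions(config: SimulationConfig, vessels: VesselNetwork,
                            n: int, on_fraction: float) -> np.ndarray:
    """Cell centroids with a known on-vessel placement fraction.

    Each cell is placed exactly on a random capsule surface with probability
    ``on_fraction`` and uniformly over the field otherwise.  Used for
    parameter-recovery checks of the association analysis.
    """
    if not 0.0 <= on_fraction <= 1.0:
        raise ValueError("on_fraction must be in [0, 1]")
    if on_fraction > 0 and vessels.n_segments == 0:
        raise ValueError("on-vessel placement requires a non-empty network")
    rng = _rng(config, "cells")
    hi = np.array(config.field_size_um)
    out = np.empty((n, 3))
    lengths = np.linalg.norm(vessels.p1 - vessels.p0, axis=1) if vessels.n_segments else None
    for i in range(n):
        if rng.random() < on_fraction:
            seg = int(rng.integers(vessels.n_segments))
            u = (vessels.p1[seg] - vessels.p0[seg]) / lengths[seg]
            s = rng.uniform(0.0, lengths[seg])
            ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            e1 = np.cross(u, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            p = vessels.p0[seg] + s * u + vessels.radii[seg] * (np.cos(phi) * e1 + np.sin(phi) * e2)
            out[i] = np.clip(p, 0.0, hi)
        else:
            out[i] = rng.random(3) * hi
    return out


def generate_depth_cohort(n_brains: int, cells_per_brain: int, p_superficial: float,
                          seed: int = 0, superficial_limit: float = 0.25) -> List[np.ndarray]:
    """Per-brain relative-depth samples with a controlled superficial mass.

    Each cell falls uniformly in the superficial band [0, superficial_limit)
    with probability ``p_superficial`` and uniformly in the remainder
    otherwise, so the expected bin-1 fraction of a four-bin histogram equals
    ``p_superficial`` exactly.  Emulates a knockdown experiment in which
    vessel-guided delivery to the superficial cortical plate is impaired.
    """
    rng = np.random.default_rng(seed)
    brains = []
    for _ in range(n_brains):
        sup = rng.random(cells_per_brain) < p_superficial
        d = np.where(sup,
                     rng.uniform(0.0, superficial_limit, cells_per_brain),
                     rng.uniform(superficial_limit, 1.0, cells_per_brain))
        brains.append(d)
    return brains


def blob_sigma_um(volume_um3: float) -> float:
    """Gaussian sigma whose half-max isosurface encloses ``volume_um3``.

    The half-max radius of ``A * exp(-r^2 / (2 sigma^2))`` is
    ``sigma * sqrt(2 ln 2)``; solving (4/3) pi r^3 = V for sigma.
    """
    r_half = (3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return r_half / np.sqrt(2.0 * np.log(2.0))


def _voxel_centers(shape, voxel_size):
    """Per-axis 1D physical centre coordinates for a (Z, Y, X) grid."""
    return [(np.arange(shape[i]) + 0.5) * voxel_size[i] for i in range(3)]


def rasterize_points(points_xyz: np.ndarray, shape, voxel_size_um,
                     sigma_um: float, amplitude: float) -> np.ndarray:
    """Render isotropic Gaussian blobs into a (Z, Y, X) float array."""
    vol = np.zeros(shape, dtype=np.float64)
    zc, yc, xc = _voxel_centers(shape, voxel_size_um)
    reach = 4.0 * sigma_um
    for x, y, z in np.atleast_2d(points_xyz):
        zi = np.searchsorted(zc, [z - reach, z + reach])
        yi = np.searchsorted(yc, [y - reach, y + reach])
        xi = np.searchsorted(xc, [x - reach, x + reach])
        if zi[0] >= zi[1] or yi[0] >= yi[1] or xi[0] >= xi[1]:
            continue
        dz = zc[zi[0]:zi[1]] - z
        dy = yc[yi[0]:yi[1]] - y
        dx = xc[xi[0]:xi[1]] - x
        g = np.exp(-(dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2)
                   / (2.0 * sigma_um ** 2))
        vol[zi[0]:zi[1], yi[0]:yi[1], xi[0]:xi[1]] += amplitude * g
    return vol


def rasterize_capsules(vessels: VesselNetwork, shape, voxel_size_um) -> np.ndarray:
    """Boolean (Z, Y, X) occupancy: voxel centres within one radius of an axis."""
    occ = np.zeros(shape, dtype=bool)
    if vessels.n_segments == 0:
        return occ
    zc, yc, xc = _voxel_centers(shape, voxel_size_um)
    for k in range(vessels.n_segments):
        p0, p1, r = vessels.p0[k], vessels.p1[k], vessels.radii[k]
        lo = np.minimum(p0, p1) - r - 1.0
        hi = np.maximum(p0, p1) + r + 1.0
        zi = np.searchsorted(zc, [lo[2], hi[2]])
        yi = np.searchsorted(yc, [lo[1], hi[1]])
        xi = np.searchsorted(xc, [lo[0], hi[0]])
        if zi[0] >= zi[1] or yi[0] >= yi[1] or xi[0] >= xi[1]:
            continue
        Z, Y, X = np.meshgrid(zc[zi[0]:zi[1]], yc[yi[0]:yi[1]], xc[xi[0]:xi[1]], indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        d = _points_to_segments(pts, p0[None, :], p1[None, :])[:, 0]
        occ[zi[0]:zi[1], yi[0]:yi[1], xi[0]:xi[1]] |= (d <= r).reshape(Z.shape)
    return occ


def rasterize(vessels: VesselNetwork, tracks: Sequence[Track], frame_index: int,
              config: SimulationConfig, nuclei: Optional[np.ndarray] = None) -> VolumeStack:
    """Render one time frame as a multi-channel intensity volume.

    Channels: ``vessels`` (union of capsules), ``cells`` (Gaussian blobs at
    the frame positions of the tracks) and ``marker`` (the same blobs with
    independent noise, standing in for an astrocyte-marker co-stain; nuclei
    positions are added to ``marker`` when given).  Gaussian noise of
    ``noise_sd`` is added to every channel.
    """
    fx, fy, fz = config.field_size_um
    vz, vy, vx = config.voxel_size_um
    shape = (int(np.ceil(fz / vz)), int(np.ceil(fy / vy)), int(np.ceil(fx / vx)))
    if shape[0] * shape[1] * shape[2] > config.max_voxels:
        raise ValueError(
            f"field {config.field_size_um} at voxel size {config.voxel_size_um} needs "
            f"{shape[0] * shape[1] * shape[2]} voxels, above the limit of {config.max_voxels}")
    for tr in tracks:
        if frame_index >= tr.n_samples:
            raise IndexError(f"frame {frame_index} does not exist for track {tr.track_id}")

    voxel_size = (vz, vy, vx)
    vessel_ch = rasterize_capsules(vessels, shape, voxel_size).astype(np.float64)
    vessel_ch *= config.channel_amplitude

    positions = np.array([tr.xyz_um[frame_index] for tr in tracks]).reshape(-1, 3)
    sigma = blob_sigma_um(config.cell_blob_volume_um3)
    cell_ch = rasterize_points(positions, shape, voxel_size, sigma, config.channel_amplitude)
    marker_pts = positions if nuclei is None else np.vstack([positions, nuclei])
    marker_ch = rasterize_points(marker_pts, shape, voxel_size, sigma, config.channel_amplitude)

    if config.noise_sd > 0:
        rng = _rng(config, f"noise-{frame_index}")
        for ch in (vessel_ch, cell_ch, marker_ch):
            ch += rng.normal(0.0, config.noise_sd, size=shape)
    return VolumeStack(channels={"vessels": vessel_ch, "cells": cell_ch, "marker": marker_ch},
                       voxel_size_um=voxel_size)
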