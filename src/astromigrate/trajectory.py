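"""Per-track and per-frame motion statistics.

The analyses operate on the per-frame steps of traced cells.  Directions and
turning angles are computed in the slice plane (x, y) only, matching traces
drawn on merged ~50-um projections; speeds use the full 3D displacement by
default (``use_z=False`` restricts them to the plane, and both modes are
reported by the pipeline).  Only frames faster than the speed gate
(default 10 um/h, strict) enter the angular statistics.

Sign conventions
----------------
* Directions are degrees counter-clockwise from +x, in (-180, 180].
* Turning angles: positive means a rightward turn in the right hemisphere
  and a leftward turn in the left hemisphere (the raw signed difference is
  negated for hemisphere ``left``).
* Angles to the radial axis: lateral positive, medial negative, where
  lateral is +x in the right hemisphere and -x in the left.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .datatypes import CorticalFrame, FrameStep, Track
from .stats import TestReport, run_test

__all__ = [
    "wrap_deg",
    "frame_steps",
    "directional_changes",
    "angles_to_radial",
    "polar_summary",
    "motile_filter",
    "compare_speed_distributions",
]


def wrap_deg(angle):
    """Wrap angles (degrees) into (-180, 180]; idempotent."""
    return np.mod(np.asarray(angle, dtype=float) - 180.0, -360.0) + 180.0


def frame_steps(track: Track, config: Optional[AnalysisConfig] = None, *,
                use_z: bool = True) -> List[FrameStep]:
    """One step per consecutive sample pair.

    ``gated`` is true iff the step speed strictly exceeds
    ``config.speed_gate_umh``; the in-plane direction is ``None`` for steps
    with zero planar displacement.
    """
    config = config or AnalysisConfig()
    dt = np.diff(track.t_h)
    d = np.diff(track.xyz_um, axis=0)
    disp = np.linalg.norm(d if use_z else d[:, :2], axis=1)
    speed = disp / dt
    t_mid = (track.t_h[:-1] + track.t_h[1:]) / 2.0
    planar = np.linalg.norm(d[:, :2], axis=1)
    steps = []
    for i in range(dt.size):
        direction = float(np.degrees(np.arctan2(d[i, 1], d[i, 0]))) if planar[i] > 0 else None
        steps.append(FrameStep(
            track_id=track.track_id,
            t_mid=float(t_mid[i]),
            displacement_um=float(disp[i]),
            speed_umh=float(speed[i]),
            direction_deg=direction,
            gated=bool(speed[i] > config.speed_gate_umh),
        ))
    return steps


def _gated_directions(track: Track, config: AnalysisConfig) -> np.ndarray:
    steps = frame_steps(track, config)
    return np.array([s.direction_deg for s in steps
                     if s.gated and s.direction_deg is not None])


def directional_changes(track: Track, config: Optional[AnalysisConfig] = None) -> np.ndarray:
    """Signed frame-to-frame direction changes of consecutive gated steps.

    Sub-gate and zero-displacement steps are skipped (not interpolated), so
    the differences are taken between consecutive *analyzed* frames.  A track
    with fewer than two gated moving steps yields an empty array.
    """
    config = config or AnalysisConfig()
    dirs = _gated_directions(track, config)
    if dirs.size < 2:
        return np.empty(0)
    delta = wrap_deg(np.diff(dirs))
    if track.hemisphere == "left":
        delta = wrap_deg(-delta)
    return delta


def _signed_angle_to_axis(directions_deg: np.ndarray, frame: CorticalFrame) -> np.ndarray:
    """Signed angle between step directions and the radial axis.

    Lateral (+x in the right hemisphere, -x in the left) maps to positive.
    """
    ax, ay = frame.radial_axis
    axis_deg = np.degrees(np.arctan2(ay, ax))
    raw = wrap_deg(directions_deg - axis_deg)  # CCW positive
    signed = -raw if frame.hemisphere == "right" else raw
    return wrap_deg(signed)


def angles_to_radial(track: Track, frame: CorticalFrame,
                     config: Optional[AnalysisConfig] = None) -> np.ndarray:
    """Per gated step, signed angle between movement and the radial axis."""
    config = config or AnalysisConfig()
    dirs = _gated_directions(track, config)
    if dirs.size == 0:
        return np.empty(0)
    return _signed_angle_to_axis(dirs, frame)


def polar_summary(track: Track, frame: CorticalFrame) -> Tuple[float, Optional[float]]:
    """Net in-plane displacement from first to last sample.

    Returns ``(net_distance_um, net_direction_deg)`` with the direction
    radial-axis-referenced as in :func:`angles_to_radial`; the direction is
    ``None`` (flagged undefined) for a closed loop.
    """
    d = track.xyz_um[-1, :2] - track.xyz_um[0, :2]
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        return 0.0, None
    direction = float(np.degrees(np.arctan2(d[1], d[0])))
    return dist, float(_signed_angle_to_axis(np.array([direction]), frame)[0])


def motile_filter(tracks: Sequence[Track], config: Optional[AnalysisConfig] = None, *,
                  use_z: bool = True) -> Tuple[List[Track], List[Track]]:
    """Partition tracks into (motile, stationary).

    A track is motile iff its maximum displacement from the first position,
    over samples within the first ``motility_window_h`` hours, strictly
    exceeds ``motility_displacement_um``.
    """
    config = config or AnalysisConfig()
    motile, stationary = [], []
    for tr in tracks:
        in_window = tr.t_h - tr.t_h[0] <= config.motility_window_h
        d = tr.xyz_um[in_window] - tr.xyz_um[0]
        disp = np.linalg.norm(d if use_z else d[:, :2], axis=1)
        (motile if disp.max() > config.motility_displacement_um else stationary).append(tr)
    return motile, stationary


def compare_speed_distributions(group_a: Sequence[FrameStep], group_b: Sequence[FrameStep],
                                ) -> TestReport:
    """Welch two-sample comparison of gated frame speeds (Fig 1c-style)."""
    a = np.array([s.speed_umh for s in group_a if s.gated])
    b = np.array([s.speed_umh for s in group_b if s.gated])
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 gated frames")
    return run_test([a, b], method="welch_t", group_names=["A", "B"])
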