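"""Cortical-depth distribution of labelled astrocytes.

Detection follows the channel-product rule: the reporter channel is
multiplied voxelwise with the marker channel (so only double-positive
signal survives), thresholded, segmented into 26-connected components, and
filtered by physical volume (strictly larger than 6,000 um^3 by default).
Each surviving component containing at least one local intensity maximum of
the product yields one detection with an intensity-weighted centroid.

Relative depth maps each centroid affinely between the upper (pial-side)
and lower borders of the cortical plate, 0 at the upper border and 1 at the
lower; depths are then counted into equal-width bins (four by default, bin 1
most superficial), and per-brain bin fractions are compared across groups
with Dunnett (vs control) or Tukey (all pairs) tests.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import AnalysisConfig
from .datatypes import CellDetection, CorticalFrame, VolumeStack
from .stats import TestReport, run_test

__all__ = [
    "detect_double_positive",
    "relative_depth",
    "bin_distribution",
    "compare_bin_fractions",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def detect_double_positive(stack: VolumeStack, ch_a: str, ch_b: str, threshold: float,
                           config: Optional[AnalysisConfig] = None) -> List[CellDetection]:
    """Detect double-positive cells via the channel product and a size filter.

    The product is computed in float64 (never wrapped), thresholded, and
    segmented with 26-connectivity; components must strictly exceed
    ``config.size_filter_um3`` in physical volume and contain at least one
    local maximum of the product image.  Centroids are intensity-weighted
    (product weights) physical (x, y, z) positions.
    """
    config = config or AnalysisConfig()
    for ch in (ch_a, ch_b):
        if ch not in stack.channels:
            raise KeyError(f"channel {ch!r} not in stack ({sorted(stack.channels)})")
    a = np.asarray(stack.channels[ch_a], dtype=np.float64)
    b = np.asarray(stack.channels[ch_b], dtype=np.float64)
    product = a * b
    fg = product >= threshold
    if not fg.any():
        return []
    labels, n = ndimage.label(fg, structure=_CONN26)
    # local maxima of the product restricted to the foreground
    maxfilt = ndimage.maximum_filter(product, size=3, mode="constant", cval=-np.inf)
    is_max = fg & (product == maxfilt)
    voxel_vol = stack.voxel_volume_um3
    detections: List[CellDetection] = []
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    max_labels = np.unique(labels[is_max])
    vz, vy, vx = stack.voxel_size_um
    for lab in range(1, n + 1):
        vol = counts[lab] * voxel_vol
        if vol <= config.size_filter_um3 or lab not in max_labels:
            continue
        idx = np.argwhere(labels == lab)
        w = product[tuple(idx.T)]
        centroid_zyx = (idx * w[:, None]).sum(axis=0) / w.sum()
        centroid = ((centroid_zyx + 0.5) * np.array([vz, vy, vx]))[::-1]
        detections.append(CellDetection(
            cell_id=f"d{len(detections):04d}",
            centroid_um=tuple(float(c) for c in centroid),
            volume_um3=float(vol),
            mean_intensity={ch_a: float(a[tuple(idx.T)].mean()),
                            ch_b: float(b[tuple(idx.T)].mean())},
        ))
    return detections


def relative_depth(detections: Sequence[CellDetection], frame: CorticalFrame,
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Relative position of each detection between the CP borders.

    Returns ``(depths, in_range)``: depth 0 at the upper (pial-side) border,
    1 at the lower border.  Out-of-range cells are flagged ``in_range=False``
    and must be excluded from binning.
    """
    if not detections:
        return np.empty(0), np.empty(0, dtype=bool)
    xy = np.array([d.centroid_um[:2] for d in detections])
    s = frame.depth_coordinate(xy)
    depth = (s - frame.upper_border_um) / (frame.lower_border_um - frame.upper_border_um)
    in_range = (depth >= 0.0) & (depth <= 1.0)
    return depth, in_range


def bin_distribution(depths: Sequence[float], config: Optional[AnalysisConfig] = None,
                     ) -> np.ndarray:
    """Count relative depths into equal-width bins.

    Bin 1 is most superficial (depth near 0).  Internal edges are half-open
    with the boundary value going to the deeper bin (depth 0.25 with four
    bins falls in bin 2); the last bin is closed at 1.  Counts always sum to
    the number of input depths.
    """
    config = config or AnalysisConfig()
    d = np.asarray(depths, dtype=float)
    if d.size and (d.min() < 0.0 or d.max() > 1.0):
        raise ValueError("depths must be within [0, 1]; filter out-of-range cells first")
    edges = np.linspace(0.0, 1.0, config.n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return counts


def compare_bin_fractions(groups: Sequence[Sequence[np.ndarray]], bin_index: int,
                          method: str = "dunnett", control_index: int = 0,
                          group_names: Optional[Sequence[str]] = None,
                          config: Optional[AnalysisConfig] = None) -> TestReport:
    """Compare one bin's per-brain fractions across groups.

    ``groups`` is a sequence of groups, each a sequence of per-brain depth
    arrays — the brain is the unit of analysis.  For each brain the fraction
    of its cells in ``bin_index`` (0-based) is computed, and the fractions
    are compared with Dunnett (against ``control_index``) or Tukey tests.
    Groups with a single brain are rejected for inference.
    """
    config = config or AnalysisConfig()
    if method not in ("dunnett", "tukey"):
        raise ValueError("method must be 'dunnett' or 'tukey'")
    fractions = []
    for group in groups:
        if len(group) < 2:
            raise ValueError("each group needs >= 2 brains for inference; "
                             "report descriptives only for single-brain groups")
        per_brain = []
        for depths in group:
            counts = bin_distribution(depths, config)
            total = counts.sum()
            per_brain.append(counts[bin_index] / total if total else 0.0)
        fractions.append(np.array(per_brain))
    return run_test(fractions, method=method, control_index=control_index,
                    group_names=group_names, unit_of_analysis="per-brain")
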