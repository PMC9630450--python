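"""File formats.

Tracks travel as CSV with the header
``track_id,hemisphere,frame,t_h,x_um,y_um,z_um,true_mode,contact`` (one row
per sample) or as TrackMate-dialect XML (spots + edges; physical units
required — pixel-calibrated files are a hard error).  Vessel geometry is CSV
``segment_id,x0,y0,z0,x1,y1,z1,radius_um``.  Volumes are one multi-page
TIFF per channel with the voxel size recorded in a sidecar JSON — TIFF tags
are never trusted as the sole source of physical calibration.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import tifffile

from .datatypes import DistanceRecord, Track, VesselNetwork, VolumeStack

__all__ = [
    "write_tracks_csv", "read_tracks_csv", "read_trackmate_xml",
    "write_vessels_csv", "read_vessels_csv",
    "write_volume", "read_volume",
    "write_distances_csv",
]

TRACK_COLUMNS = ["track_id", "hemisphere", "frame", "t_h", "x_um", "y_um", "z_um",
                 "true_mode", "contact"]


def write_tracks_csv(tracks: Sequence[Track], path: str | Path) -> int:
    """Write tracks in the canonical CSV dialect; returns the row count."""
    rows = []
    for tr in tracks:
        for i in range(tr.n_samples):
            rows.append({
                "track_id": tr.track_id,
                "hemisphere": tr.hemisphere,
                "frame": i,
                "t_h": tr.t_h[i],
                "x_um": tr.xyz_um[i, 0],
                "y_um": tr.xyz_um[i, 1],
                "z_um": tr.xyz_um[i, 2],
                "true_mode": tr.true_mode if tr.true_mode is not None else "",
                "contact": ("" if tr.contact is None else int(tr.contact[i])),
            })
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False)
    return len(df)


def read_tracks_csv(path: str | Path) -> List[Track]:
    df = pd.read_csv(path, dtype={"track_id": str, "true_mode": str, "contact": "object"})
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        contact_raw = g["contact"]
        has_contact = contact_raw.notna().all() and not (contact_raw.astype(str) == "").any()
        mode = g["true_mode"].iloc[0]
        tracks.append(Track(
            track_id=str(tid),
            hemisphere=str(g["hemisphere"].iloc[0]),
            t_h=g["t_h"].to_numpy(float),
            xyz_um=g[["x_um", "y_um", "z_um"]].to_numpy(float),
            true_mode=None if (pd.isna(mode) or mode == "") else str(mode),
            contact=(contact_raw.astype(float).astype(bool).to_numpy()
                     if has_contact else None),
        ))
    return tracks


_PHYSICAL_UNITS = {"um", "µm", "micron", "microns", "micrometer", "micrometre",
                   "micrometers", "micrometres"}


def read_trackmate_xml(path: str | Path, hemisphere: str = "right") -> List[Track]:
    """Read a TrackMate-dialect XML file (spots + edges) into tracks.

    Spatial units must be physical (micrometres); frame times come from
    ``POSITION_T`` (assumed seconds when the time unit says so, converted to
    hours).  Files calibrated in pixels are rejected.
    """
    root = ET.parse(str(path)).getroot()
    model = root.find("Model")
    if model is None:
        raise ValueError("not a TrackMate file: no <Model> element")
    sunits = (model.get("spatialunits") or "").strip().lower()
    if sunits not in _PHYSICAL_UNITS:
        raise ValueError(
            f"TrackMate file uses spatial units {sunits!r}; physical micrometres are required")
    tunits = (model.get("timeunits") or "sec").strip().lower()
    t_scale = {"sec": 1 / 3600.0, "s": 1 / 3600.0, "second": 1 / 3600.0,
               "seconds": 1 / 3600.0, "min": 1 / 60.0, "minute": 1 / 60.0,
               "minutes": 1 / 60.0, "h": 1.0, "hour": 1.0, "hours": 1.0}.get(tunits)
    if t_scale is None:
        raise ValueError(f"unsupported TrackMate time unit {tunits!r}")

    spots = {}
    for spot in model.iter("Spot"):
        sid = spot.get("ID")
        spots[sid] = (
            float(spot.get("POSITION_T")) * t_scale,
            float(spot.get("POSITION_X")),
            float(spot.get("POSITION_Y")),
            float(spot.get("POSITION_Z", 0.0)),
        )
    tracks = []
    for tr in model.iter("Track"):
        tid = tr.get("TRACK_ID") or tr.get("name") or f"t{len(tracks)}"
        ids = set()
        for edge in tr.iter("Edge"):
            ids.add(edge.get("SPOT_SOURCE_ID"))
            ids.add(edge.get("SPOT_TARGET_ID"))
        samples = sorted((spots[i] for i in ids if i in spots), key=lambda s: s[0])
        if len(samples) < 2:
            continue
        arr = np.array(samples)
        tracks.append(Track(track_id=str(tid), hemisphere=hemisphere,
                            t_h=arr[:, 0], xyz_um=arr[:, 1:4]))
    return tracks


def write_vessels_csv(network: VesselNetwork, path: str | Path) -> int:
    df = pd.DataFrame(network.segments,
                      columns=["x0", "y0", "z0", "x1", "y1", "z1", "radius_um"])
    df.insert(0, "segment_id", [f"s{i:04d}" for i in range(len(df))])
    df.to_csv(path, index=False)
    return len(df)


def read_vessels_csv(path: str | Path) -> VesselNetwork:
    df = pd.read_csv(path)
    cols = ["x0", "y0", "z0", "x1", "y1", "z1", "radius_um"]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"vessel CSV missing columns: {sorted(missing)}")
    return VesselNetwork(df[cols].to_numpy(float))


def write_volume(stack: VolumeStack, directory: str | Path, prefix: str = "volume") -> List[Path]:
    """Write one TIFF per channel plus a voxel-size sidecar JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in stack.channels.items():
        p = directory / f"{prefix}_{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        paths.append(p)
    sidecar = directory / f"{prefix}_voxel_size.json"
    sidecar.write_text(json.dumps({
        "voxel_size_um": {"z": stack.voxel_size_um[0], "y": stack.voxel_size_um[1],
                          "x": stack.voxel_size_um[2]},
        "axis_order": "ZYX",
        "channels": sorted(stack.channels),
    }, indent=2))
    paths.append(sidecar)
    return paths


def read_volume(directory: str | Path, prefix: str = "volume") -> VolumeStack:
    """Read the channel TIFFs back; the sidecar JSON is the voxel-size authority."""
    directory = Path(directory)
    sidecar = directory / f"{prefix}_voxel_size.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"voxel-size sidecar {sidecar} is required")
    meta = json.loads(sidecar.read_text())
    v = meta["voxel_size_um"]
    channels: Dict[str, np.ndarray] = {}
    for name in meta["channels"]:
        p = directory / f"{prefix}_{name}.tif"
        channels[name] = tifffile.imread(p).astype(np.float64)
    return VolumeStack(channels=channels, voxel_size_um=(v["z"], v["y"], v["x"]))


def write_distances_csv(records: Sequence[DistanceRecord], path: str | Path) -> int:
    rows = [{
        "cell_id": r.cell_id,
        "x": r.centroid_um[0], "y": r.centroid_um[1], "z": r.centroid_um[2],
        "distance_um": r.distance_um,
        "included": int(r.included),
        "reason": r.exclusion_reason,
    } for r in records]
    pd.DataFrame(rows, columns=["cell_id", "x", "y", "z", "distance_um", "included",
                                "reason"]).to_csv(path, index=False)
    return len(rows)
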