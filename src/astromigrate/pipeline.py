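"""End-to-end orchestration: simulate -> analyze -> report.

Stages write plain-text artifacts (CSV/JSON, TIFF volumes) into one output
directory and a ``RunManifest`` records the resolved configuration, seeds,
per-stage outputs with content hashes and row counts, and the package
version, so a deterministic stage re-run reproduces its hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .config import AnalysisConfig, SimulationConfig, dump_config
from .datatypes import CorticalFrame, Track
from . import io as amio
from . import synthetic, trajectory, vessels as vesselmod, distribution as distmod
from .stats import run_test

__all__ = ["RunManifest", "run_pipeline", "STAGES"]

STAGES = ("simulate", "track-stats", "vessel-dist", "classify", "distribution", "report")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: Dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: Dict[str, Path], counts: Dict[str, int],
               elapsed_s: float) -> None:
        self.stages[stage] = {
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
            "row_counts": counts,
            "elapsed_s": round(elapsed_s, 3),
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "version": self.version,
             "stages": self.stages}, indent=2) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _default_frame(sim: SimulationConfig, hemisphere: str = "right") -> CorticalFrame:
    # pial surface at y = field height; depth coordinate is -y
    fy = sim.field_size_um[1]
    return CorticalFrame(radial_axis=(0.0, 1.0), upper_border_um=-fy,
                         lower_border_um=0.0, hemisphere=hemisphere)


def _require(out_dir: Path, name: str, stage: str) -> Path:
    p = out_dir / name
    if not p.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires missing upstream output {p}; run the producing stage first")
    return p


def run_pipeline(sim: SimulationConfig, ana: AnalysisConfig, out_dir: str | Path,
                 stages: Optional[Sequence[str]] = None, seed: Optional[int] = None,
                 log=print) -> RunManifest:
    """Run the requested stages in dependency order.

    ``seed`` overrides ``sim.seed`` when given.  Partial subsets are allowed
    when the upstream outputs already exist in ``out_dir``; a missing
    dependency raises ``FileNotFoundError`` naming the file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        sim = sim.model_copy(update={"seed": seed})
    stages = list(stages) if stages else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    stages.sort(key=STAGES.index)

    manifest = RunManifest(config={"simulation": sim.model_dump(), "analysis": ana.model_dump()},
                           seed=sim.seed)
    dump_config(sim, ana, out_dir / "resolved_config.json")

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            outputs, counts = _stage_simulate(sim, out_dir)
        elif stage == "track-stats":
            outputs, counts = _stage_track_stats(sim, ana, out_dir)
        elif stage == "vessel-dist":
            outputs, counts = _stage_vessel_dist(sim, ana, out_dir)
        elif stage == "classify":
            outputs, counts = _stage_classify(sim, ana, out_dir)
        elif stage == "distribution":
            outputs, counts = _stage_distribution(sim, ana, out_dir)
        else:
            outputs, counts = _stage_report(sim, ana, out_dir)
        dt = time.perf_counter() - t0
        manifest.record(stage, outputs, counts, dt)
        log(f"[{stage}] done in {dt:.2f}s: " +
            ", ".join(f"{k}={v}" for k, v in counts.items()))
    manifest.write(out_dir / "manifest.json")
    return manifest


def _stage_simulate(sim: SimulationConfig, out_dir: Path):
    network = synthetic.generate_vessel_network(sim)
    tracks = synthetic.generate_tracks(sim, network)
    nuclei = synthetic.generate_nuclei(sim, n=2000)
    stack = synthetic.rasterize(network, tracks, frame_index=0, config=sim, nuclei=None)

    n_seg = amio.write_vessels_csv(network, out_dir / "vessels.csv")
    n_rows = amio.write_tracks_csv(tracks, out_dir / "tracks.csv")
    np.savetxt(out_dir / "nuclei.csv", nuclei, delimiter=",", header="x_um,y_um,z_um",
               comments="")
    vol_paths = amio.write_volume(stack, out_dir, prefix="frame0")
    outputs = {"vessels": out_dir / "vessels.csv", "tracks": out_dir / "tracks.csv",
               "nuclei": out_dir / "nuclei.csv"}
    outputs.update({f"volume_{p.name}": p for p in vol_paths})
    return outputs, {"segments": n_seg, "track_rows": n_rows, "nuclei": len(nuclei)}


def _stage_track_stats(sim: SimulationConfig, ana: AnalysisConfig, out_dir: Path):
    import pandas as pd

    tracks = amio.read_tracks_csv(_require(out_dir, "tracks.csv", "track-stats"))
    rows = []
    summaries = {}
    for tr in tracks:
        frame = _default_frame(sim, tr.hemisphere)
        steps = trajectory.frame_steps(tr, ana)
        turns = trajectory.directional_changes(tr, ana)
        angles = trajectory.angles_to_radial(tr, frame, ana)
        gated_idx = [i for i, s in enumerate(steps) if s.gated and s.direction_deg is not None]
        turn_map = dict(zip(gated_idx[1:], turns))
        angle_map = dict(zip(gated_idx, angles))
        for i, s in enumerate(steps):
            rows.append({
                "track_id": s.track_id, "t_mid": s.t_mid, "speed_umh": s.speed_umh,
                "gated": int(s.gated),
                "direction_deg": s.direction_deg if s.direction_deg is not None else "",
                "turn_deg": turn_map.get(i, ""),
                "angle_to_radial_deg": angle_map.get(i, ""),
            })
        net_dist, net_dir = trajectory.polar_summary(tr, frame)
        motile = trajectory.motile_filter([tr], ana)[0]
        summaries[tr.track_id] = {
            "hemisphere": tr.hemisphere,
            "true_mode": tr.true_mode,
            "n_samples": tr.n_samples,
            "n_gated": int(sum(s.gated for s in steps)),
            "n_zero_displacement": int(sum(s.direction_deg is None for s in steps)),
            "net_distance_um": net_dist,
            "net_direction_deg": net_dir,
            "motile": bool(motile),
        }
    df = pd.DataFrame(rows, columns=["track_id", "t_mid", "speed_umh", "gated",
                                     "direction_deg", "turn_deg", "angle_to_radial_deg"])
    df.to_csv(out_dir / "frame_stats.csv", index=False)
    (out_dir / "track_summaries.json").write_text(json.dumps(summaries, indent=2))
    outputs = {"frame_stats": out_dir / "frame_stats.csv",
               "track_summaries": out_dir / "track_summaries.json"}
    return outputs, {"frame_rows": len(df), "tracks": len(tracks)}


def _load_mask(sim: SimulationConfig, ana: AnalysisConfig, out_dir: Path, stage: str):
    stack = amio.read_volume(out_dir, prefix="frame0")
    threshold = sim.channel_amplitude / 2.0
    return stack, vesselmod.build_vessel_mask(stack, "vessels", threshold, ana)


def _stage_vessel_dist(sim: SimulationConfig, ana: AnalysisConfig, out_dir: Path):
    _require(out_dir, "frame0_voxel_size.json", "vessel-dist")
    tracks = amio.read_tracks_csv(_require(out_dir, "tracks.csv", "vessel-dist"))
    nuclei = np.loadtxt(_require(out_dir, "nuclei.csv", "vessel-dist"),
                        delimiter=",", skiprows=1)
    stack, mask = _load_mask(sim, ana, out_dir, "vessel-dist")

    cells = np.array([tr.xyz_um[0] for tr in tracks])
    ids = [tr.track_id for tr in tracks]
    records = vesselmod.nearest_vessel_distance(cells, mask, cell_ids=ids)
    records = vesselmod.apply_edge_exclusion(records, sim.field_size_um, ana)
    n = amio.write_distances_csv(records, out_dir / "distances.csv")

    ref = vesselmod.nearest_vessel_distance(nuclei, mask)
    ref = vesselmod.apply_edge_exclusion(ref, sim.field_size_um, ana)
    amio.write_distances_csv(ref, out_dir / "distances_reference.csv")

    frac, hist = vesselmod.association_fraction(records, ana)
    ref_frac, _ = vesselmod.association_fraction(ref, ana)
    (out_dir / "association.json").write_text(json.dumps({
        "association_fraction_cells": frac,
        "association_fraction_reference": ref_frac,
        "threshold_um": ana.association_threshold_um,
        "histogram_counts": hist["counts"].tolist(),
        "histogram_edges": hist["edges"].tolist(),
    }, indent=2))
    outputs = {"distances": out_dir / "distances.csv",
               "distances_reference": out_dir / "distances_reference.csv",
               "association": out_dir / "association.json"}
    return outputs, {"cells": n, "reference_nuclei": len(ref)}


def _stage_classify(sim: SimulationConfig, ana: AnalysisConfig, out_dir: Path):
    import pandas as pd

    tracks = amio.read_tracks_csv(_require(out_dir, "tracks.csv", "classify"))
    _require(out_dir, "frame0_voxel_size.json", "classify")
    stack, mask = _load_mask(sim, ana, out_dir, "classify")
    rows = []
    persistence = {}
    field_pairs = []
    for tr in tracks:
        labels = vesselmod.classify_track_contacts(tr, mask, ana)
        for i, lab in enumerate(labels):
            rows.append({"track_id": tr.track_id, "frame": i, "on_vessel": int(lab)})
        persistence[tr.track_id] = vesselmod.on_vessel_persistence(tr, labels, ana)
        field_pairs.append((tr, labels))
    ratios = vesselmod.off_on_ratio({"field0": field_pairs}, ana)
    df = pd.DataFrame(rows, columns=["track_id", "frame", "on_vessel"])
    df.to_csv(out_dir / "contacts.csv", index=False)
    (out_dir / "classification.json").write_text(json.dumps({
        "on_vessel_max_distance_um": persistence,
        "off_on_ratios": [{"field": r.field_id, "n_on": r.n_on, "n_off": r.n_off,
                           "n_excluded": r.n_excluded, "ratio": r.ratio} for r in ratios],
    }, indent=2))
    outputs = {"contacts": out_dir / "contacts.csv",
               "classification": out_dir / "classification.json"}
    return outputs, {"contact_rows": len(df),
                     "selected_persistent": sum(v is not None for v in persistence.values())}


def _stage_distribution(sim: SimulationConfig, ana: AnalysisConfig, out_dir: Path):
    import pandas as pd

    _require(out_dir, "frame0_voxel_size.json", "distribution")
    stack = amio.read_volume(out_dir, prefix="frame0")
    threshold = (sim.channel_amplitude ** 2) / 4.0  # half-max radius of the blob product
    detections = distmod.detect_double_positive(stack, "cells", "marker", threshold, ana)
    frame = _default_frame(sim)
    depths, in_range = distmod.relative_depth(detections, frame)
    counts = distmod.bin_distribution(depths[in_range], ana)
    rows = []
    for det, depth, ok in zip(detections, depths, in_range):
        b = int(min(np.floor(depth * ana.n_bins), ana.n_bins - 1)) + 1 if ok else ""
        rows.append({"cell_id": det.cell_id, "x": det.centroid_um[0], "y": det.centroid_um[1],
                     "z": det.centroid_um[2], "volume_um3": det.volume_um3,
                     "depth_rel": depth, "bin": b})
    df = pd.DataFrame(rows, columns=["cell_id", "x", "y", "z", "volume_um3",
                                     "depth_rel", "bin"])
    df.to_csv(out_dir / "detections.csv", index=False)
    (out_dir / "bin_counts.json").write_text(json.dumps({
        "n_bins": ana.n_bins, "counts": counts.tolist(),
        "n_out_of_range": int((~in_range).sum()),
    }, indent=2))
    outputs = {"detections": out_dir / "detections.csv",
               "bin_counts": out_dir / "bin_counts.json"}
    return outputs, {"detections": len(df), "binned": int(counts.sum())}


def _stage_report(sim: SimulationConfig, ana: AnalysisConfig, out_dir: Path):
    tracks = amio.read_tracks_csv(_require(out_dir, "tracks.csv", "report"))
    by_mode: Dict[str, List[Track]] = {}
    for tr in tracks:
        by_mode.setdefault(tr.true_mode or "unknown", []).append(tr)
    report: Dict[str, dict] = {}
    if "erratic" in by_mode and "radial" in by_mode:
        steps_e = [s for tr in by_mode["erratic"] for s in trajectory.frame_steps(tr, ana)]
        steps_r = [s for tr in by_mode["radial"] for s in trajectory.frame_steps(tr, ana)]
        report["speed_welch"] = trajectory.compare_speed_distributions(
            steps_e, steps_r).to_dict()
        ang_e = np.concatenate([
            trajectory.angles_to_radial(tr, _default_frame(sim, tr.hemisphere), ana)
            for tr in by_mode["erratic"]])
        ang_r = np.concatenate([
            trajectory.angles_to_radial(tr, _default_frame(sim, tr.hemisphere), ana)
            for tr in by_mode["radial"]])
        report["angle_mannwhitney"] = run_test(
            [np.abs(ang_e), np.abs(ang_r)], method="mann_whitney",
            group_names=["erratic", "radial"], unit_of_analysis="per-frame").to_dict()
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return {"report": out_dir / "report.json"}, {"tests": len(report)}
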