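"""Configuration objects for the simulator and the analysis pipeline.

Two validated configuration models are exposed:

``SimulationConfig``
    Parameters of the synthetic slice-imaging generator: field geometry,
    acquisition timing, per-mode kinematic parameters of the three migration
    classes (erratic, radial, vessel-guided), vessel-network geometry and
    rasterization settings.

``AnalysisConfig``
    Every numeric threshold used by the analysis modules: the 10 um/h speed
    gate, the 20 um motility displacement filter, the 5 h on-vessel
    persistence minimum, the 10 h traceability filter, the 5 um vessel
    association threshold, the 15 um Z and 20 um XY edge exclusions, the
    6,000 um^3 detection size filter and the four-bin depth histogram.

Both models reject unknown keys, so a typo in a JSON config file is a hard
error rather than a silently ignored setting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["SimulationConfig", "AnalysisConfig", "load_config", "dump_config"]


class SimulationConfig(BaseModel):
    """Parameters of the synthetic time-lapse and volume generator.

    Units are physical throughout: micrometres, hours, and um/h.  The
    coordinate frame is right-handed with +y pointing radially toward the
    pial surface, x the mediolateral in-slice axis and z the imaging depth;
    arrays are indexed (Z, Y, X).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    duration_h: float = Field(24.0, gt=0)
    frame_interval_h: float = Field(0.25, ge=10.0 / 60.0, le=30.0 / 60.0)
    field_size_um: Tuple[float, float, float] = (300.0, 300.0, 50.0)
    n_cells_per_mode: int = Field(10, ge=0)

    # erratic migration: fast, weakly persistent, net surface-ward drift
    erratic_speed_mean_umh: float = Field(30.0, gt=0)
    erratic_speed_sd: float = Field(10.0, ge=0)
    erratic_turn_sd_deg: float = Field(60.0, ge=0)
    erratic_drift_umh: float = Field(3.0, ge=0)

    # radial migration: slower, strongly directed toward the surface
    radial_speed_mean_umh: float = Field(12.0, gt=0)
    radial_speed_sd: float = Field(4.0, ge=0)
    radial_turn_sd_deg: float = Field(10.0, ge=0)

    # vessel-guided migration
    vessel_guided_speed_umh: float = Field(15.0, gt=0)
    attach_prob_per_frame: float = Field(0.3, ge=0.0, le=1.0)
    detach_prob_per_frame: float = Field(0.02, ge=0.0, le=1.0)
    capture_radius_um: float = Field(5.0, gt=0)

    # vessel network
    vessel_n_segments: int = Field(30, ge=0)
    vessel_radius_um: float = Field(2.0, gt=0)
    vessel_radial_bias: float = Field(0.7, ge=0.0, le=1.0)

    # rasterization
    voxel_size_um: Tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x)
    cell_blob_volume_um3: float = Field(8000.0, gt=0)
    channel_amplitude: float = Field(100.0, gt=0)
    noise_sd: float = Field(1.0, ge=0)
    max_voxels: int = Field(300_000_000, gt=0)

    @model_validator(mode="after")
    def _check_geometry(self) -> "SimulationConfig":
        if any(s <= 0 for s in self.field_size_um):
            raise ValueError("field_size_um extents must be strictly positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be strictly positive")
        return self

    @property
    def n_frames(self) -> int:
        """Number of acquired frames, including the initial one."""
        return int(round(self.duration_h / self.frame_interval_h)) + 1


class AnalysisConfig(BaseModel):
    """Numeric thresholds of the quantitative analyses."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    speed_gate_umh: float = Field(10.0, ge=0)
    motility_displacement_um: float = Field(20.0, ge=0)
    motility_window_h: float = Field(24.0, gt=0)
    min_on_vessel_h: float = Field(5.0, ge=0)
    traceability_min_h: float = Field(10.0, ge=0)
    association_threshold_um: float = Field(5.0, ge=0)
    z_exclusion_um: float = Field(15.0, ge=0)
    xy_margin_um: float = Field(20.0, ge=0)
    size_filter_um3: float = Field(6000.0, ge=0)
    n_bins: int = Field(4, ge=1)
    contact_tolerance_um: float = Field(0.0, ge=0)
    histogram_bin_um: float = Field(2.5, gt=0)
    min_component_voxels: int = Field(8, ge=0)


def load_config(path: str | Path) -> tuple[SimulationConfig, AnalysisConfig]:
    """Read a JSON config file with optional ``simulation``/``analysis`` sections.

    Unknown keys anywhere in the file raise ``pydantic.ValidationError``.
    """
    raw = json.loads(Path(path).read_text())
    extra = set(raw) - {"simulation", "analysis"}
    if extra:
        raise ValueError(f"unknown top-level config sections: {sorted(extra)}")
    sim = SimulationConfig(**raw.get("simulation", {}))
    ana = AnalysisConfig(**raw.get("analysis", {}))
    return sim, ana


def dump_config(sim: SimulationConfig, ana: AnalysisConfig, path: str | Path) -> None:
    """Write the fully resolved configuration back to disk."""
    payload = {"simulation": sim.model_dump(), "analysis": ana.model_dump()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
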