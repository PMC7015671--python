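"""YAML run configuration and provenance records.

``RunConfig`` is a strict schema (unknown keys are rejected) holding the
stage parameters of the whole pipeline with every seed explicit, so a
run is reproducible from its config file alone. ``write_provenance``
drops a JSON record (config hash, seeds, version) next to each output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = ["RunConfig", "write_provenance"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LatticeConfig(_Strict):
    n_pf: int = 14
    start_number: int = 3
    monomer_rise_A: float = 40.95
    radius_A: float = 110.0
    pf_skew_deg: float = 0.0
    seam_index: int = 0
    handedness: int = -1


class DensityConfig(_Strict):
    voxel_size_A: float = 4.0
    box_px: int = 96
    motor_occupancy: float = 1.0
    tail_occupancy: float = 0.0
    motor_radius_offset_A: float = 30.0
    tail_radius_offset_A: float = 55.0


class SimulateConfig(_Strict):
    n_filaments: int = 4
    filament_len_A: float = 1200.0
    spacing_A: float = 80.0
    snr: float = 0.1
    with_ctf: bool = False
    defocus_um: float = 1.5
    seed: int = 0


class RefineConfig(_Strict):
    angular_step_deg: float = 4.0
    shift_range_A: float = 10.0
    n_iter: int = 4
    twist_tol_deg: float = 0.01
    rise_tol_A: float = 0.01
    seed: int = 0


class ValidateConfig(_Strict):
    fsc_threshold: float = 0.143
    local_threshold: float = 0.5
    bfactor_A2: float = -200.0
    window_A: float = 100.0


class RunConfig(_Strict):
    schema_version: int = 1
    seed: int = 0
    lattice: LatticeConfig = LatticeConfig()
    density: DensityConfig = DensityConfig()
    simulate: SimulateConfig = SimulateConfig()
    refine: RefineConfig = RefineConfig()
    validation: ValidateConfig = ValidateConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.model_validate(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def write_provenance(path, config: RunConfig, stage: str, extra: dict | None = None) -> None:
    from mtrecon import __version__

    rec = {
        "stage": stage,
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }
    if extra:
        rec.update(extra)
    Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
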