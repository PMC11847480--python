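"""Run configuration: a schema-validated YAML file drives the pipeline.

Unknown keys are rejected (``extra="forbid"``) so typos fail loudly before
any computation; the canonical JSON serialization of the config is hashed
into every output artifact for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["AnalysisParams", "DomainConfig", "MonitorConfig", "RunConfig",
           "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DomainConfig(_Strict):
    label: str
    chain: str
    residues: list[tuple[int, int]]


class MonitorConfig(_Strict):
    label: str
    kind: Literal["distance", "hbond", "contact"]
    atom_1: str  # selection expression resolving to one atom (donor for hbond)
    atom_2: str
    cutoff: Optional[float] = None


class AnalysisParams(_Strict):
    probe_radius: float = 1.4  # Å, water probe
    n_points: int = 960
    radii_set: str = "chothia"
    contact_threshold: float = 38.0  # Å^2, interface-residue rule
    hbond_distance_cutoff: float = 3.5
    hbond_angle_cutoff: float = 30.0
    contact_cutoff: float = 4.5
    k_min: int = 1
    k_max: int = 6
    n_restarts: int = 5
    landscape_bins: int = 32
    temperature: float = 310.0  # K
    dt: float = 1.0  # ns between trajectory frames
    bsa_interval_ns: float = 1.0
    angle_definition: Literal["vertex-at-ligand", "axis-to-com"] = \
        "vertex-at-ligand"
    mass_weighted_com: bool = True


class RunConfig(_Strict):
    topology: Optional[str] = None
    trajectory: Optional[str] = None
    synthetic_preset: Optional[str] = None
    synthetic_frames: Optional[int] = None
    seed: int = 0
    output_dir: str = "complexdyn_out"
    domains: list[DomainConfig] = Field(default_factory=list)
    ligand: Optional[str] = None  # domain label
    receptor_a: Optional[tuple[str, str]] = None  # (domain, domain) labels
    receptor_b: Optional[tuple[str, str]] = None
    monitors: list[MonitorConfig] = Field(default_factory=list)
    analysis: AnalysisParams = Field(default_factory=AnalysisParams)

    @model_validator(mode="after")
    def _check_inputs(self):
        file_mode = self.trajectory is not None
        if file_mode == (self.synthetic_preset is not None):
            raise ValueError(
                "exactly one of trajectory or synthetic_preset must be set"
            )
        if file_mode and not (self.ligand and self.receptor_a and self.receptor_b):
            raise ValueError(
                "file-based runs must name the ligand and both receptor "
                "domain pairs"
            )
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def preflight(config: RunConfig) -> None:
    """Validate referenced input files before touching any outputs."""
    for label, path in (("topology", config.topology),
                        ("trajectory", config.trajectory)):
        if path is not None and not Path(path).is_file():
            raise FileNotFoundError(f"{label} file not found: {path}")
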