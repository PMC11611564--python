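"""Serializable case description: the scripted surgical plan.

A case file (YAML or JSON) records every input of a design run — meshes,
voxel size, ROI, resection masks, fill method, segmenting planes, surgical
approaches, clearance, flanges, porous architecture, evaluation toggles and
DICOM overlay — so a run is fully reproducible from the file alone.  The
schema is versioned and strict: unknown keys are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PlaneModel(_Strict):
    point: tuple[float, float, float]
    normal: tuple[float, float, float]


class RoiModel(_Strict):
    base_center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float = Field(gt=0)
    height: float = Field(gt=0)


class MaskModel(_Strict):
    shape: Literal["sphere", "box", "mesh"]
    center: tuple[float, float, float] | None = None
    radius: float | None = None
    lo: tuple[float, float, float] | None = None
    hi: tuple[float, float, float] | None = None
    path: str | None = None
    translation: tuple[float, float, float] | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.shape == "sphere" and (self.center is None or self.radius is None):
            raise ValueError("sphere mask needs center and radius")
        if self.shape == "box" and (self.lo is None or self.hi is None):
            raise ValueError("box mask needs lo and hi")
        if self.shape == "mesh" and self.path is None:
            raise ValueError("mesh mask needs a path")
        return self


class SegmentalFillModel(_Strict):
    method: Literal["segmental"] = "segmental"
    plane_a: PlaneModel
    plane_b: PlaneModel
    profile_control_values: list[float] = Field(default=[1.0, 1.0])
    guide_points: list[tuple[float, float, float]] | None = None
    n_sections: int = 32
    snap_tol: float = 5.0


class ClosingFillModel(_Strict):
    method: Literal["minor_closing"] = "minor_closing"
    distance: float = Field(gt=0)


class GuidedFillModel(_Strict):
    method: Literal["guided"] = "guided"
    opening_plane: PlaneModel
    guide_points: list[list[tuple[float, float, float]]] = Field(default_factory=list)
    depth: float | None = None  # explicit plug depth for through-holes


class ApproachModel(_Strict):
    direction: tuple[float, float, float]
    sweep_factor: float = 1.5


class ArchitectureModel(_Strict):
    family: Literal["tpms", "lattice", "voronoi"]
    variant: str | None = None
    cell_size: float = 4.0
    thickness: float = 0.8
    shell_thickness: float = 0.0
    n_seeds: int = 64


class EvaluationModel(_Strict):
    porosity: bool = True
    pore_size: bool = True
    insertion_steps: int = 50


class DicomModel(_Strict):
    series_dir: str
    delta: int = 300
    anonymise: bool = True


class CaseDescription(_Strict):
    """Top-level case file schema (version 1)."""

    version: int = SCHEMA_VERSION
    name: str = "case"
    voxel_size: float = Field(gt=0, default=0.5)
    rng_seed: int = 0
    defect_mesh: str
    hardware_mesh: str | None = None
    roi: RoiModel | None = None
    masks: list[MaskModel] = Field(default_factory=list)
    fill: SegmentalFillModel | ClosingFillModel | GuidedFillModel = Field(
        discriminator="method")
    split_planes: list[PlaneModel] = Field(default_factory=list)
    approach: ApproachModel | None = None
    approaches: list[ApproachModel] | None = None
    clearance: float = Field(ge=0, default=0.1)
    flange_meshes: list[str] = Field(default_factory=list)
    flange_demarcation: PlaneModel | None = None
    architecture: ArchitectureModel | Literal["solid"] = "solid"
    evaluation: EvaluationModel = Field(default_factory=EvaluationModel)
    dicom: DicomModel | None = None
    output_dir: str = "out"

    @model_validator(mode="after")
    def _check(self):
        if self.version != SCHEMA_VERSION:
            raise ValueError(f"unsupported case schema version {self.version}")
        if self.approach is None and not self.approaches:
            raise ValueError("a surgical approach is required "
                             "(approach or approaches)")
        if self.approach is not None and self.approaches:
            raise ValueError("give either approach or approaches, not both")
        if self.flange_meshes and self.flange_demarcation is None:
            raise ValueError("flanges need a demarcation plane")
        return self


def load_case(path) -> CaseDescription:
    """Load and validate a YAML or JSON case file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return CaseDescription.model_validate(data)


def save_case(case: CaseDescription, path) -> None:
    path = Path(path)
    data = case.model_dump(mode="json", exclude_none=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
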