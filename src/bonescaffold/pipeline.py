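"""Case-driven design pipeline: import -> ROI -> resection -> fill ->
split -> approach subtraction -> flanges -> porous -> export -> evaluation
-> DICOM overlay.

Each stage writes its artifacts as soon as they exist, so a failed run
retains everything up to the failing stage; failures abort with the stage
named.  Re-running a case with identical inputs and seeds is bit-identical
for meshes and reports (all randomness is seeded, mesh extraction is
deterministic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import levelset as lv
from . import mesh_io
from .case import CaseDescription
from .evaluate import pore_size_distribution, porosity, virtual_insertion
from .fill import (
    BezierProfile,
    CrossSectionPlane,
    GuideCurve,
    guided_cavity_fill,
    minor_cavity_fill,
    segmental_fill,
)
from .porous import ArchitectureSpec, make_porous
from .resection import MaskStack, RoiCylinder, add_mask, apply_resection, isolate_roi
from .shaping import ScaffoldDesign, SurgicalApproach, add_flanges, scaffold_from_fill, split_by_planes

__all__ = ["run_case", "StageError", "RunResult"]


class StageError(RuntimeError):
    """Pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunResult:
    output_dir: Path
    designs: list[ScaffoldDesign] = field(default_factory=list)
    porous: list = field(default_factory=list)
    reports: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)


def _plane(m) -> CrossSectionPlane:
    return CrossSectionPlane(tuple(m.point), tuple(m.normal))


def run_case(case: CaseDescription, base_dir=".") -> RunResult:
    """Execute a validated case description; returns designs and reports."""
    base = Path(base_dir)
    out = base / case.output_dir
    out.mkdir(parents=True, exist_ok=True)
    h = case.voxel_size
    lv.reset_op_counts()
    log: dict = {"case": case.name, "voxel_size": h, "rng_seed": case.rng_seed,
                 "stages": []}
    result = RunResult(output_dir=out, log=log)

    def stage(name):
        log["stages"].append(name)
        return name

    def fail(name, exc):
        _write_log(out, log, error=f"[{name}] {exc}")
        raise StageError(name, str(exc)) from exc

    # ---- import ---------------------------------------------------------
    name = stage("import")
    try:
        defect_mesh = mesh_io.read_mesh(base / case.defect_mesh)
        hardware_mesh = (mesh_io.read_mesh(base / case.hardware_mesh)
                         if case.hardware_mesh else None)
        defect_ls = lv.mesh_to_levelset(defect_mesh, h=h)
        hardware_ls = (lv.mesh_to_levelset(hardware_mesh, h=h)
                       if hardware_mesh is not None else None)
    except Exception as exc:
        fail(name, exc)

    # ---- ROI isolation --------------------------------------------------
    if case.roi is not None:
        name = stage("roi")
        try:
            roi = RoiCylinder(tuple(case.roi.base_center), tuple(case.roi.axis),
                              case.roi.radius, case.roi.height)
            defect_ls = isolate_roi(defect_ls, roi)
        except Exception as exc:
            fail(name, exc)

    # ---- resection ------------------------------------------------------
    if case.masks:
        name = stage("resection")
        try:
            stack = MaskStack()
            for i, m in enumerate(case.masks):
                if m.shape == "sphere":
                    solid = lv.sphere(m.center, m.radius, h)
                elif m.shape == "box":
                    solid = lv.box(m.lo, m.hi, h)
                else:
                    solid = lv.mesh_to_levelset(mesh_io.read_mesh(base / m.path), h=h)
                stack = add_mask(stack, solid, pose=m.translation,
                                 mask_id=f"{case.name}-mask-{i}")
            defect_ls = apply_resection(defect_ls, stack)
        except Exception as exc:
            fail(name, exc)

    # ---- fill -----------------------------------------------------------
    name = stage("fill")
    try:
        f = case.fill
        if f.method == "segmental":
            guide = GuideCurve(np.asarray(f.guide_points)) if f.guide_points else None
            fill_ls = segmental_fill(
                defect_mesh, _plane(f.plane_a), _plane(f.plane_b),
                profile=BezierProfile(f.profile_control_values),
                guide=guide, n_sections=f.n_sections, h=h, snap_tol=f.snap_tol)
        elif f.method == "minor_closing":
            closed = minor_cavity_fill(defect_ls, f.distance)
            # stand the fill a quarter voxel off the bone so the coincident
            # closed/defect surfaces do not leave speckle in the fill mesh
            fill_ls = lv.difference(closed, lv.offset(defect_ls, 0.25 * h))
        else:
            guides = [GuideCurve(np.asarray(g)) for g in f.guide_points]
            fill_ls = guided_cavity_fill(defect_mesh, _plane(f.opening_plane),
                                         guides=guides, h=h, depth=f.depth)
        if fill_ls.is_empty():
            raise ValueError("fill stage produced empty geometry")
        mesh_io.write_mesh(lv.levelset_to_mesh(fill_ls), out / "fill.stl")
    except StageError:
        raise
    except Exception as exc:
        fail(name, exc)

    # ---- split ----------------------------------------------------------
    pieces = [fill_ls]
    if case.split_planes:
        name = stage("split")
        try:
            pieces = split_by_planes(fill_ls, [_plane(p) for p in case.split_planes])
        except Exception as exc:
            fail(name, exc)

    approaches = (case.approaches if case.approaches
                  else [case.approach] * len(pieces))
    if len(approaches) != len(pieces):
        fail("split", ValueError(
            f"{len(pieces)} pieces but {len(approaches)} approaches"))

    # ---- approach subtraction ------------------------------------------
    name = stage("approach")
    designs = []
    try:
        for i, (piece, ap) in enumerate(zip(pieces, approaches)):
            approach = SurgicalApproach(tuple(ap.direction), ap.sweep_factor)
            design = scaffold_from_fill(piece, defect_ls, approach,
                                        clearance=case.clearance,
                                        hardware=hardware_ls)
            designs.append(design)
            mesh_io.write_mesh(lv.levelset_to_mesh(design.solid),
                               out / f"scaffold_solid_{i}.stl")
    except Exception as exc:
        fail(name, exc)

    # ---- flanges --------------------------------------------------------
    if case.flange_meshes:
        name = stage("flanges")
        try:
            flanges = [lv.mesh_to_levelset(mesh_io.read_mesh(base / p), h=h)
                       for p in case.flange_meshes]
            designs[0] = add_flanges(designs[0], flanges,
                                     _plane(case.flange_demarcation))
            mesh_io.write_mesh(lv.levelset_to_mesh(designs[0].solid),
                               out / "scaffold_solid_0.stl")
        except Exception as exc:
            fail(name, exc)
    result.designs = designs

    # ---- porous ---------------------------------------------------------
    porous_sets = []
    if case.architecture != "solid":
        name = stage("porous")
        try:
            a = case.architecture
            for i, design in enumerate(designs):
                spec = ArchitectureSpec(
                    family=a.family, variant=a.variant, cell_size=a.cell_size,
                    thickness=a.thickness, shell_thickness=a.shell_thickness,
                    n_seeds=a.n_seeds, rng_seed=case.rng_seed)
                por = make_porous(design.solid, spec,
                                  flange_region=design.flange_region)
                design.porous = por
                porous_sets.append(por)
                mesh_io.write_mesh(lv.levelset_to_mesh(por),
                                   out / f"scaffold_porous_{i}.stl")
        except Exception as exc:
            fail(name, exc)
    result.porous = porous_sets

    # ---- printability ---------------------------------------------------
    name = stage("printability")
    try:
        quality = {}
        for stl in sorted(out.glob("*.stl")):
            rep = mesh_io.check_printability(mesh_io.read_mesh(stl))
            quality[stl.name] = rep.as_dict()
        result.reports["printability"] = quality
    except Exception as exc:
        fail(name, exc)

    # ---- evaluation -----------------------------------------------------
    name = stage("evaluation")
    try:
        ev = case.evaluation
        obstruction = (lv.union(defect_ls, hardware_ls) if hardware_ls is not None
                       else defect_ls)
        per_design = []
        for i, design in enumerate(designs):
            entry = {}
            if ev.porosity and design.porous is not None:
                entry["porosity"] = porosity(design.porous, design.solid).as_dict()
            if ev.pore_size and design.porous is not None:
                entry["pore_size"] = pore_size_distribution(
                    design.porous, design.solid).as_dict()
            if ev.insertion_steps > 0:
                entry["insertion"] = virtual_insertion(
                    design, obstruction, steps=ev.insertion_steps).as_dict()
            per_design.append(entry)
        result.reports["evaluation"] = per_design
    except Exception as exc:
        fail(name, exc)

    # ---- DICOM overlay --------------------------------------------------
    if case.dicom is not None:
        name = stage("dicom_overlay")
        try:
            from .dicom_overlay import overlay_scaffold, read_dicom_series, write_dicom_series

            vol = read_dicom_series(base / case.dicom.series_dir)
            meshes = [lv.levelset_to_mesh(d.porous if d.porous is not None
                                          else d.solid) for d in designs]
            overlaid = overlay_scaffold(vol, meshes, delta=case.dicom.delta)
            write_dicom_series(overlaid, out / "dicom_overlay",
                               anonymise=case.dicom.anonymise)
        except Exception as exc:
            fail(name, exc)

    log["op_counts"] = lv.reset_op_counts()
    _write_log(out, log)
    with open(out / "reports.json", "w") as fjson:
        json.dump(result.reports, fjson, indent=2)
    return result


def _write_log(out: Path, log: dict, error: str | None = None) -> None:
    payload = dict(log)
    if error:
        payload["error"] = error
    with open(out / "run_log.json", "w") as f:
        json.dump(payload, f, indent=2, default=str)
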