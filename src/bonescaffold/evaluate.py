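"""Scaffold evaluation: porosity, pore-size distribution, virtual insertion.

Volumes use sub-voxel-corrected counting (each voxel contributes the
fraction ``clip(1/2 - phi/h, 0, 1)``), consistent with the kernel's
volume measure.  Pore sizes use the granulometry / local-thickness
convention: the diameter assigned to a pore voxel is that of the largest
inscribed sphere (within pore space) containing it, computed by
morphological openings at increasing radii.  Virtual insertion retraces
the scaffold backwards along the approach direction and reports the worst
interpenetration with the obstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .levelset import LevelSet, _common_grid, boolean, to_grid, translate, volume
from .shaping import ScaffoldDesign

__all__ = ["PorosityReport", "PoreSizeDistribution", "InsertionReport",
           "porosity", "pore_size_distribution", "virtual_insertion",
           "min_surface_distance"]


@dataclass
class PorosityReport:
    envelope_volume: float
    material_volume: float
    porosity: float

    def as_dict(self) -> dict:
        return {"envelope_volume_mm3": self.envelope_volume,
                "material_volume_mm3": self.material_volume,
                "porosity": self.porosity}


@dataclass
class PoreSizeDistribution:
    bin_edges: np.ndarray  # mm, len = nbins + 1
    pore_volume_per_bin: np.ndarray  # mm^3
    method: str = "local-thickness (granulometry by opening)"

    @property
    def total_pore_volume(self) -> float:
        return float(self.pore_volume_per_bin.sum())

    def mode_diameter(self) -> float:
        if self.pore_volume_per_bin.sum() == 0:
            return float("nan")
        i = int(np.argmax(self.pore_volume_per_bin))
        return float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2)

    def as_dict(self) -> dict:
        return {"bin_edges_mm": self.bin_edges.tolist(),
                "pore_volume_per_bin_mm3": self.pore_volume_per_bin.tolist(),
                "method": self.method}


@dataclass
class InsertionReport:
    steps: int
    collision_free: bool
    max_penetration: float  # mm
    tolerance: float
    per_step_penetration: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"steps": self.steps, "collision_free": self.collision_free,
                "max_penetration_mm": self.max_penetration,
                "tolerance_mm": self.tolerance}


def porosity(porous: LevelSet, envelope: LevelSet) -> PorosityReport:
    """Void fraction of the porous scaffold within its envelope."""
    env_vol = volume(envelope)
    if env_vol <= 0:
        raise ValueError("envelope is empty")
    mat = boolean("intersection", porous, envelope)
    mat_vol = volume(mat)
    p = float(np.clip(1.0 - mat_vol / env_vol, 0.0, 1.0))
    return PorosityReport(envelope_volume=env_vol, material_volume=mat_vol,
                          porosity=p)


def pore_size_distribution(porous: LevelSet, envelope: LevelSet,
                           nbins: int | None = None) -> PoreSizeDistribution:
    """Histogram of pore diameters weighted by pore volume.

    Pore space is envelope minus material (open boundary pores included).
    Each pore voxel is labelled with the diameter of the largest opening
    (erosion radius r that survives, dilated back) containing it; radii are
    swept on the voxel scale from large to small so every voxel gets the
    largest applicable sphere.
    """
    h = porous.h
    pore = boolean("difference", envelope, porous)
    mask = pore.indicator()
    if not mask.any():
        return PoreSizeDistribution(bin_edges=np.array([0.0, h]),
                                    pore_volume_per_bin=np.array([0.0]))

    # inscribed-sphere radius at every pore voxel (voxel units)
    edt_in = ndi.distance_transform_edt(mask)
    rmax = int(np.ceil(edt_in.max()))
    thick = np.zeros(mask.shape, dtype=np.float32)
    for r in range(rmax, 0, -1):
        seeds = edt_in >= r  # centers of inscribed spheres of radius r
        if not seeds.any():
            continue
        # dilate the seed set by r: voxels covered by such a sphere
        cover = ndi.distance_transform_edt(~seeds) <= r
        newly = cover & mask & (thick == 0)
        thick[newly] = 2 * r * h  # diameter in mm

    diam = thick[mask]
    vols = np.full(diam.shape, h**3)
    if nbins is None:
        nbins = max(1, min(32, rmax))
    edges = np.linspace(0.0, max(diam.max(), h), nbins + 1)
    hist, edges = np.histogram(diam, bins=edges, weights=vols)
    return PoreSizeDistribution(bin_edges=edges, pore_volume_per_bin=hist)


def virtual_insertion(design: ScaffoldDesign, obstruction: LevelSet,
                      steps: int = 50, tolerance: float | None = None
                      ) -> InsertionReport:
    """Retrace the insertion path and measure worst interpenetration.

    At each step the scaffold is translated by -t * direction (its pose
    t mm before seating) and intersected with the obstruction; penetration
    is how far scaffold material reaches into the obstruction (the most
    negative obstruction signed distance over scaffold-interior voxel
    centers).  Poses are snapped to the voxel lattice, so a design built by
    the shaping sweep measures exactly zero; the default tolerance of half
    a voxel absorbs resampling noise of externally supplied geometry while
    still catching single-voxel violations (center sampling understates the
    true depth by up to one voxel).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    h = design.solid.h
    tol = tolerance if tolerance is not None else 0.5 * h
    d = np.asarray(design.approach.direction)
    L = design.provenance.get("sweep_length_mm")
    if L is None:
        L = design.approach.sweep_factor * obstruction.extent(d)

    max_pen = 0.0
    per_step = []
    for k in range(steps + 1):
        t = L * k / steps
        # snap the pose to the voxel lattice: exact shift, no resampling blur
        v = np.round(-t * d / h) * h
        moved = translate(design.solid, v)
        grid = _common_grid(moved, obstruction)
        mv = to_grid(moved, grid).values
        ov = to_grid(obstruction, grid).values
        inside = mv < 0
        pen = float(max(0.0, -ov[inside].min())) if inside.any() else 0.0
        per_step.append(pen)
        max_pen = max(max_pen, pen)
    return InsertionReport(steps=steps, collision_free=bool(max_pen <= tol),
                           max_penetration=max_pen, tolerance=tol,
                           per_step_penetration=per_step)


def _surface_points(mesh, spacing: float) -> np.ndarray:
    from . import _raster

    verts = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces)
    edges = verts[faces[:, 1]] - verts[faces[:, 0]]
    if float(np.median(np.linalg.norm(edges, axis=1))) <= spacing:
        # triangles already finer than the sampling: vertices suffice
        return np.concatenate([verts, mesh.triangles_center])
    return _raster.sample_surface(verts, faces, spacing)


def min_surface_distance(mesh_a, mesh_b, sample_spacing: float) -> float:
    """Minimum surface-to-surface distance between two meshes, by dense
    point sampling of both surfaces (error below ``sample_spacing``)."""
    from scipy.spatial import cKDTree

    pa = _surface_points(mesh_a, sample_spacing)
    pb = _surface_points(mesh_b, sample_spacing)
    if len(pa) > len(pb):
        pa, pb = pb, pa
    dist, _ = cKDTree(pb).query(pa, workers=-1)
    return float(dist.min())
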