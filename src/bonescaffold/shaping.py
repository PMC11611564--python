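"""Insertion-aware scaffold shaping.

The central safety requirement of a patient-specific scaffold is that it
can actually be inserted: translated into place along the chosen surgical
approach direction without hitting host bone or retained hardware.  The
forbidden volume is the swept shadow of the obstruction along the
insertion travel direction; subtracting it (dilated by a small clearance)
from the fill envelope guarantees an unobstructed path.

The sweep itself is computed in the level-set domain by iterative
translate-and-union with a compounding (doubling) step schedule: iteration
k translates the running union by 2^(k-1) voxels, so a sweep of length L
takes ceil(log2(L/h + 1)) unions instead of L/h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fill import CrossSectionPlane
from .levelset import (
    LevelSet,
    boolean,
    grid_from_bounds,
    halfspace,
    offset,
    to_grid,
    translate,
)

__all__ = ["SurgicalApproach", "ScaffoldDesign", "sweep", "scaffold_from_fill",
           "split_by_planes", "add_flanges"]


@dataclass(frozen=True)
class SurgicalApproach:
    """Insertion direction (unit vector, the scaffold's direction of travel
    toward the bone) and the sweep length as a multiple of the defect
    extent along that direction."""

    direction: tuple[float, float, float]
    sweep_factor: float = 1.5

    def __post_init__(self):
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError("approach direction must be nonzero")
        object.__setattr__(self, "direction", tuple(np.asarray(self.direction) / n))
        if self.sweep_factor < 1.0:
            raise ValueError("sweep_factor must be >= 1")


@dataclass
class ScaffoldDesign:
    """A designed scaffold piece: solid envelope, optional porous version,
    optional solid flange region, and the insertion parameters used."""

    solid: LevelSet
    approach: SurgicalApproach
    clearance: float = 0.0
    porous: LevelSet | None = None
    flange_region: LevelSet | None = None
    provenance: dict = field(default_factory=dict)


def sweep_steps(length: float, h: float) -> list[float]:
    """The compounding translation schedule: h, 2h, 4h, ... plus one final
    partial step so the total equals ``length`` exactly."""
    steps = []
    total = 0.0
    step = h
    while total + step <= length + 1e-9 * h:
        steps.append(step)
        total += step
        step *= 2.0
    rem = length - total
    if rem > 1e-9 * h:
        steps.append(rem)
    return steps


def sweep(ls: LevelSet, direction, length: float, clip_bounds=None) -> LevelSet:
    """Union of all translates of ``ls`` along ``direction`` over [0, length].

    Swept at voxel resolution with the doubling schedule (each iteration
    unions the running result with itself translated by twice the previous
    distance).  Axis-aligned sweeps are lattice-exact; oblique directions
    translate with trilinear resampling.  ``clip_bounds`` optionally crops
    the growing grid to a world AABB of interest after each union.
    """
    if length < 0:
        raise ValueError("sweep length must be >= 0")
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("sweep direction must be nonzero")
    d = d / n
    if length == 0:
        return ls.copy()

    out = ls.copy()
    for step in sweep_steps(length, ls.h):
        moved = translate(out, d * step)
        out = boolean("union", out, moved)
        if clip_bounds is not None:
            grid = grid_from_bounds(np.asarray(clip_bounds[0]),
                                    np.asarray(clip_bounds[1]), out.h,
                                    out.grid.band_width)
            out = to_grid(out, grid)
    return out


def scaffold_from_fill(fill: LevelSet, defect: LevelSet,
                       approach: SurgicalApproach,
                       clearance: float = 0.1,
                       hardware: LevelSet | None = None) -> ScaffoldDesign:
    """Make the fill insertable: subtract the clearance-dilated swept shadow
    of bone (and hardware) along the insertion direction.

    The obstruction is swept along the travel direction: the scaffold at a
    pre-seating pose S - t*d collides with obstruction O exactly when S
    meets O + t*d, so forbidden volume = union of O + t*d over t in [0, L]
    with L = sweep_factor * extent(obstruction along d).
    """
    if fill.is_empty():
        raise ValueError("fill is empty")
    if clearance < 0:
        raise ValueError("clearance must be >= 0")
    obstruction = defect if hardware is None else boolean("union", defect, hardware)
    d = np.asarray(approach.direction)
    L = approach.sweep_factor * obstruction.extent(d)

    lo, hi = fill.interior_bounds()
    margin = (clearance + (fill.grid.band_width + 2) * fill.h)
    clip = (lo - margin, hi + margin)
    shadow = sweep(obstruction, d, L, clip_bounds=clip)
    if clearance > 0:
        shadow = offset(shadow, clearance)
    solid = boolean("difference", fill, shadow)
    if solid.is_empty():
        raise ValueError("fill entirely shadowed: no insertable scaffold volume "
                         "remains along this approach")
    return ScaffoldDesign(solid=solid, approach=approach, clearance=clearance,
                          provenance={"sweep_length_mm": float(L)})


def split_by_planes(fill: LevelSet, planes: list[CrossSectionPlane]) -> list[LevelSet]:
    """Partition the fill into pieces by half-space sign cells of the planes.

    Pieces are voxel-disjoint and union back to the fill exactly (each
    interior voxel belongs to exactly one sign cell).  Empty cells are
    dropped; typical parallel segmenting planes yield len(planes)+1 pieces.
    """
    pieces = [fill.copy()]
    for pl in planes:
        hs = halfspace(pl.point, pl.normal, fill.grid)
        # voxel centers exactly on the plane belong to the "below" piece
        hs.values -= np.float32(1e-6 * fill.h)
        nxt = []
        for piece in pieces:
            below = boolean("intersection", piece, hs)
            above = boolean("difference", piece, hs)
            for cand in (below, above):
                if not cand.is_empty():
                    nxt.append(cand)
        pieces = nxt
    return pieces if pieces else [fill.copy()]


def add_flanges(design: ScaffoldDesign, flanges: list[LevelSet],
                demarcation_plane: CrossSectionPlane) -> ScaffoldDesign:
    """Union fixation flanges onto the solid and record the flange region.

    The demarcation plane separates the scaffold body (to be made porous)
    from the flanges (kept fully solid); its normal points toward the
    flange side.
    """
    if not flanges:
        return design
    solid = design.solid
    for fl in flanges:
        if fl.is_empty():
            raise ValueError("flange solid is empty")
        if boolean("intersection", solid, fl).is_empty():
            warnings.warn("flange does not touch the scaffold solid (floating flange)")
        solid = boolean("union", solid, fl)
    # material on the side the normal points to: (x - p) . n >= 0
    hs = halfspace(demarcation_plane.point, demarcation_plane.normal, solid.grid)
    flange_region = boolean("difference", solid, hs)
    if flange_region.is_empty():
        warnings.warn("demarcation plane leaves an empty flange region")
    return ScaffoldDesign(solid=solid, approach=design.approach,
                          clearance=design.clearance, porous=design.porous,
                          flange_region=flange_region,
                          provenance=dict(design.provenance))
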