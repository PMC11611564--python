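"""Virtual surgical resection: ROI isolation and an undoable mask stack.

The surgeon's plan is expressed as an ordered list of posed mask solids
(spheres, boxes, or any imported closed mesh).  The resected region is the
Boolean union of all committed masks; applying the resection subtracts
that union from the defect geometry.  Committed masks are immutable and
identified by unique tokens; the stack supports undo, so the whole
process is non-destructive and reproducible from the case file.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .levelset import LevelSet, boolean, empty_like, from_sdf

_mask_counter = itertools.count(1)


@dataclass(frozen=True)
class RoiCylinder:
    """Region-of-interest cylinder: ``base_center`` is the center of the base
    disk, ``axis`` points toward the top along ``height``."""

    base_center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float
    height: float

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("ROI cylinder radius and height must be > 0")
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-6:
            object.__setattr__(self, "axis", tuple(np.asarray(self.axis) / n))


@dataclass(frozen=True)
class Mask:
    id: str
    solid: LevelSet


@dataclass
class MaskStack:
    """Ordered, undoable collection of committed resection masks."""

    masks: list[Mask] = field(default_factory=list)

    def resected_union(self, grid_like: LevelSet) -> LevelSet:
        """Union of all committed masks, on a grid compatible with
        ``grid_like`` (empty union -> empty level set)."""
        out = empty_like(grid_like.grid)
        for m in self.masks:
            out = boolean("union", out, m.solid)
        return out

    def __len__(self):
        return len(self.masks)


def isolate_roi(defect: LevelSet, roi: RoiCylinder) -> LevelSet:
    """Intersect the defect with the ROI cylinder solid."""
    from .levelset import cylinder

    cyl = cylinder(roi.base_center, roi.axis, roi.radius, roi.height,
                   h=defect.h, band_width=defect.grid.band_width)
    out = boolean("intersection", defect, cyl)
    if out.is_empty():
        warnings.warn("ROI cylinder does not intersect the defect geometry")
    return out


def add_mask(stack: MaskStack, solid: LevelSet, pose: np.ndarray | None = None,
             mask_id: str | None = None) -> MaskStack:
    """Commit a copy of the mask in its current position; returns a new stack.

    ``pose`` is an optional rigid translation (3-vector, mm) applied before
    committing; rotations should be baked into the solid by the caller.
    """
    if solid.is_empty():
        raise ValueError("cannot commit an empty mask solid")
    if pose is not None:
        from .levelset import translate

        solid = translate(solid, np.asarray(pose, dtype=float))
    mid = mask_id if mask_id is not None else f"mask-{next(_mask_counter):06d}"
    if any(m.id == mid for m in stack.masks):
        raise ValueError(f"mask id {mid!r} already committed")
    return MaskStack(masks=[*stack.masks, Mask(mid, solid)])


def undo_mask(stack: MaskStack) -> MaskStack:
    """Remove the last committed mask; a warning (not an error) when empty."""
    if not stack.masks:
        warnings.warn("undo on an empty mask stack is a no-op")
        return MaskStack(masks=list(stack.masks))
    return MaskStack(masks=list(stack.masks[:-1]))


def apply_resection(defect: LevelSet, stack: MaskStack) -> LevelSet:
    """Subtract the union of all committed masks from the defect."""
    if not stack.masks:
        return defect.copy()
    return boolean("difference", defect, stack.resected_union(defect))


def current_masked_region(defect: LevelSet, mask: LevelSet) -> LevelSet:
    """Live preview: the part of the defect the currently posed mask would
    remove (defect ∩ mask)."""
    return boolean("intersection", defect, mask)
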