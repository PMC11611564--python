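"""Porous scaffold architectures.

Converts a solid scaffold envelope into an open-porous structure for bone
ingrowth.  Three families:

* **TPMS** sheet solids (gyroid, schwarz-P, neovius): material where
  ``|F(2*pi*x/cell)| <= iso``, with ``iso`` calibrated numerically per
  variant so the sheet wall measures ``thickness`` mm.
* **Periodic strut lattices** (sc, bcc, fcc): material within
  ``thickness/2`` of the unit-cell edge network, tiled over the solid.
* **Voronoi strut networks**: seeds sampled uniformly inside the solid
  (seeded RNG, bit-reproducible), ridge edges of the Voronoi diagram
  thickened into struts.

Every architecture is intersected with the solid envelope; an optional
outer contour shell (the boundary skin of the solid) is unioned on, and a
flange region supplied by the shaping stage is kept fully solid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import Voronoi, cKDTree

from . import _raster
from .levelset import LevelSet, boolean, offset

__all__ = ["ArchitectureSpec", "tpms_scaffold", "lattice_scaffold",
           "voronoi_scaffold", "make_porous"]

_TPMS_VARIANTS = ("gyroid", "schwarz", "neovius")
_LATTICE_VARIANTS = ("sc", "bcc", "fcc")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Porous architecture parameters.

    ``thickness`` is the TPMS wall thickness or strut diameter (mm);
    ``cell_size`` the periodic cell edge (mm); ``variant`` one of the TPMS
    or lattice names, ignored for voronoi; ``n_seeds``/``rng_seed`` apply
    to voronoi only; ``shell_thickness`` > 0 adds the outer contour skin.
    """

    family: str
    variant: str | None = None
    cell_size: float = 4.0
    thickness: float = 0.8
    shell_thickness: float = 0.0
    n_seeds: int = 64
    rng_seed: int = 0
    sheet: bool = True  # TPMS sheet solid (|F|<=iso) vs network solid (F<=iso)

    def __post_init__(self):
        if self.family not in ("tpms", "lattice", "voronoi"):
            raise ValueError(f"unknown architecture family {self.family!r}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if not (0 < self.thickness < self.cell_size):
            raise ValueError("need 0 < thickness < cell_size")
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")
        if self.family == "tpms" and self.variant not in _TPMS_VARIANTS:
            raise ValueError(f"unknown TPMS variant {self.variant!r}")
        if self.family == "lattice" and self.variant not in _LATTICE_VARIANTS:
            raise ValueError(f"unknown lattice variant {self.variant!r}")
        if self.family == "voronoi" and self.n_seeds < 2:
            raise ValueError("voronoi needs n_seeds >= 2")


# ---------------------------------------------------------------------------
# TPMS
# ---------------------------------------------------------------------------

def tpms_value(variant: str, X, Y, Z):
    """Implicit TPMS function on dimensionless coordinates (period 2*pi)."""
    if variant == "gyroid":
        return (np.sin(X) * np.cos(Y) + np.sin(Y) * np.cos(Z)
                + np.sin(Z) * np.cos(X))
    if variant == "schwarz":
        return np.cos(X) + np.cos(Y) + np.cos(Z)
    if variant == "neovius":
        return 3.0 * (np.cos(X) + np.cos(Y) + np.cos(Z)) \
            + 4.0 * np.cos(X) * np.cos(Y) * np.cos(Z)
    raise ValueError(f"unknown TPMS variant {variant!r}")


def _tpms_grad_mag(variant: str, X, Y, Z):
    if variant == "gyroid":
        gx = np.cos(X) * np.cos(Y) - np.sin(Z) * np.sin(X)
        gy = -np.sin(X) * np.sin(Y) + np.cos(Y) * np.cos(Z)
        gz = -np.sin(Y) * np.sin(Z) + np.cos(Z) * np.cos(X)
    elif variant == "schwarz":
        gx, gy, gz = -np.sin(X), -np.sin(Y), -np.sin(Z)
    elif variant == "neovius":
        gx = -3.0 * np.sin(X) - 4.0 * np.sin(X) * np.cos(Y) * np.cos(Z)
        gy = -3.0 * np.sin(Y) - 4.0 * np.cos(X) * np.sin(Y) * np.cos(Z)
        gz = -3.0 * np.sin(Z) - 4.0 * np.cos(X) * np.cos(Y) * np.sin(Z)
    else:
        raise ValueError(variant)
    return np.sqrt(gx**2 + gy**2 + gz**2)


@lru_cache(maxsize=None)
def _surface_grad_mean(variant: str) -> float:
    """Mean |grad F| on the F=0 surface, by dense deterministic sampling of
    one period; used to map a requested wall thickness to the iso value."""
    rng = np.random.default_rng(20240917)
    pts = rng.uniform(0.0, 2 * np.pi, size=(400_000, 3))
    F = tpms_value(variant, *pts.T)
    span = float(np.abs(F).max())
    near = np.abs(F) < 0.05 * span
    return float(_tpms_grad_mag(variant, *pts[near].T).mean())


def tpms_iso(variant: str, thickness: float, cell_size: float) -> float:
    """Iso level giving a sheet of the requested wall thickness: a sheet
    |F| <= iso has local half-thickness iso / |grad_world F| with
    |grad_world F| = (2*pi/cell) |grad F|."""
    g = _surface_grad_mean(variant)
    return thickness * np.pi * g / cell_size


def tpms_scaffold(solid: LevelSet, spec: ArchitectureSpec,
                  flange_region: LevelSet | None = None) -> LevelSet:
    """TPMS sheet (or network) solid intersected with the envelope."""
    if spec.family != "tpms":
        raise ValueError("spec.family must be 'tpms'")
    grid = solid.grid
    ax = grid.axes()
    X, Y, Z = np.meshgrid(*[2 * np.pi * a / spec.cell_size for a in ax], indexing="ij")
    F = tpms_value(spec.variant, X, Y, Z)
    iso = tpms_iso(spec.variant, spec.thickness, spec.cell_size)
    g = _surface_grad_mean(spec.variant)
    scale = spec.cell_size / (2 * np.pi * g)  # approximate mm per unit of F
    if spec.sheet:
        phi = (np.abs(F) - iso) * scale
    else:
        phi = (F - iso) * scale
    B = np.float32(grid.band)
    arch = LevelSet(grid, np.clip(phi, -B, B).astype(np.float32))
    return _assemble(solid, arch, spec, flange_region)


# ---------------------------------------------------------------------------
# periodic strut lattices
# ---------------------------------------------------------------------------

def _unit_cell_edges(variant: str) -> np.ndarray:
    """Edge segments of the unit cell [0,1]^3, as (n, 2, 3)."""
    c = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                 dtype=float)
    edges = []
    # simple cubic: the 12 cube edges
    for a in range(8):
        for b in range(a + 1, 8):
            if np.sum(np.abs(c[a] - c[b])) == 1:
                edges.append((c[a], c[b]))
    if variant == "bcc":
        for a in range(8):
            b = c[a] + (1 - 2 * c[a])  # opposite corner
            if tuple(c[a]) < tuple(b):
                edges.append((c[a], b))
    elif variant == "fcc":
        for axis in range(3):
            for side in (0.0, 1.0):
                corners = c[c[:, axis] == side]
                # both diagonals of the face
                edges.append((corners[0], corners[3]))
                edges.append((corners[1], corners[2]))
    elif variant != "sc":
        raise ValueError(f"unknown lattice variant {variant!r}")
    return np.asarray(edges)


def lattice_scaffold(solid: LevelSet, spec: ArchitectureSpec,
                     flange_region: LevelSet | None = None) -> LevelSet:
    """Periodic strut lattice intersected with the envelope.

    The lattice phase is anchored at the solid's bounding-box minimum
    corner.  Distance to the periodic edge network is evaluated on one
    canonical cell (voxel coordinates folded modulo the cell), which by
    periodicity equals the distance to the full tiling.
    """
    if spec.family != "lattice":
        raise ValueError("spec.family must be 'lattice'")
    grid = solid.grid
    cell = spec.cell_size
    lo, _ = solid.interior_bounds()
    segs = _unit_cell_edges(spec.variant) * cell
    ax = grid.axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    P = np.stack([np.mod(X - lo[0], cell).ravel(),
                  np.mod(Y - lo[1], cell).ravel(),
                  np.mod(Z - lo[2], cell).ravel()], axis=1)
    dist = _raster.segments_point_distance(P, segs[:, 0], segs[:, 1])
    phi = dist.reshape(grid.shape) - spec.thickness / 2.0
    B = np.float32(grid.band)
    arch = LevelSet(grid, np.clip(phi, -B, B).astype(np.float32))
    return _assemble(solid, arch, spec, flange_region)


# ---------------------------------------------------------------------------
# Voronoi strut networks
# ---------------------------------------------------------------------------

def voronoi_scaffold(solid: LevelSet, spec: ArchitectureSpec,
                     flange_region: LevelSet | None = None) -> LevelSet:
    """Voronoi tessellation strut network inside the envelope.

    Seeds are drawn uniformly from the interior voxels with the spec's RNG
    seed, so identical seeds give bit-identical scaffolds.  Finite ridge
    edges are clipped to the solid's bounding box and thickened to struts;
    struts shorter than one voxel are dropped.
    """
    if spec.family != "voronoi":
        raise ValueError("spec.family must be 'voronoi'")
    grid = solid.grid
    h = solid.h
    rng = np.random.default_rng(spec.rng_seed)
    idx = np.argwhere(solid.values < 0)
    if len(idx) < spec.n_seeds:
        raise ValueError("solid too small for the requested number of seeds")
    pick = rng.choice(len(idx), size=spec.n_seeds, replace=False)
    o = np.asarray(grid.origin)
    seeds = o + idx[pick] * h + rng.uniform(-0.5, 0.5, size=(spec.n_seeds, 3)) * h

    vor = Voronoi(seeds)
    lo, hi = solid.interior_bounds()
    pad = spec.thickness
    segs = []
    verts = vor.vertices
    for ridge in vor.ridge_vertices:
        if -1 in ridge:
            continue
        for i in range(len(ridge)):
            a = verts[ridge[i]]
            b = verts[ridge[(i + 1) % len(ridge)]]
            seg = _clip_segment(a, b, lo - pad, hi + pad)
            if seg is not None and np.linalg.norm(seg[1] - seg[0]) >= h:
                segs.append(seg)
    if not segs:
        raise ValueError("no Voronoi struts inside the solid")
    segs = np.unique(np.round(np.asarray(segs), 9), axis=0)

    ax = grid.axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    P = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    dist = _raster.segments_point_distance(P, segs[:, 0], segs[:, 1])
    phi = dist.reshape(grid.shape) - spec.thickness / 2.0
    B = np.float32(grid.band)
    arch = LevelSet(grid, np.clip(phi, -B, B).astype(np.float32))
    return _assemble(solid, arch, spec, flange_region)


def _clip_segment(a, b, lo, hi):
    """Liang-Barsky clip of segment ab to an AABB; None when outside."""
    d = b - a
    t0, t1 = 0.0, 1.0
    for k in range(3):
        if d[k] == 0:
            if a[k] < lo[k] or a[k] > hi[k]:
                return None
            continue
        ta = (lo[k] - a[k]) / d[k]
        tb = (hi[k] - a[k]) / d[k]
        ta, tb = min(ta, tb), max(ta, tb)
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        if t0 > t1:
            return None
    return np.stack([a + t0 * d, a + t1 * d])


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _assemble(solid: LevelSet, arch: LevelSet, spec: ArchitectureSpec,
              flange_region: LevelSet | None) -> LevelSet:
    porous = boolean("intersection", solid, arch)
    if spec.shell_thickness > 0:
        eroded = offset(solid, -spec.shell_thickness)
        shell = boolean("difference", solid, eroded)
        porous = boolean("union", porous, shell)
    if flange_region is not None and not flange_region.is_empty():
        porous = boolean("union", porous,
                         boolean("intersection", solid, flange_region))
    return porous


def make_porous(solid: LevelSet, spec: ArchitectureSpec,
                flange_region: LevelSet | None = None) -> LevelSet:
    """Dispatch on the architecture family."""
    fn = {"tpms": tpms_scaffold, "lattice": lattice_scaffold,
          "voronoi": voronoi_scaffold}[spec.family]
    return fn(solid, spec, flange_region)
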