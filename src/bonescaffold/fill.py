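"""Defect-filling envelope generation.

Three fill strategies cover the clinically distinct defect shapes:

``minor_cavity_fill``
    morphological closing (dilate then erode by the same distance) of the
    defect level set: crevices and minor cavities narrower than twice the
    distance are filled while the base geometry is unaffected.

``segmental_fill``
    bridges a segmental (through) defect: the closed intersection curves
    of two user-placed cross-section planes with the bone are lofted into
    a solid, with a Bezier profile scaling the intermediate sections about
    their centroid and an optional guide curve bending the centroid path.

``guided_cavity_fill``
    closes a one-sided pocket: the opening boundary curve is capped by a
    (optionally guide-lifted) surface and the enclosed void becomes the
    fill solid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage as ndi
from scipy.special import comb

from . import _raster
from .levelset import (
    DEFAULT_BAND,
    GridSpec,
    LevelSet,
    grid_from_bounds,
    mesh_to_levelset,
    offset,
)

__all__ = [
    "CrossSectionPlane",
    "ClosedCurve",
    "BezierProfile",
    "GuideCurve",
    "minor_cavity_fill",
    "plane_mesh_intersection",
    "segmental_fill",
    "guided_cavity_fill",
]


@dataclass(frozen=True)
class CrossSectionPlane:
    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self):
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", tuple(np.asarray(self.normal) / n))

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions (deterministic)."""
        n = np.asarray(self.normal)
        ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(n, ref)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v


@dataclass
class ClosedCurve:
    """Ordered 3D polyline, implicitly closed (last point connects to first)."""

    points: np.ndarray
    plane: CrossSectionPlane | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 3:
            raise ValueError("a closed curve needs at least 3 points")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.linalg.norm(d, axis=1).sum())

    def enclosed_area(self) -> float:
        """Shoelace area of the curve projected on its best-fit plane."""
        p = self.points - self.centroid
        if self.plane is not None:
            u, v = self.plane.basis()
        else:
            _, _, vt = np.linalg.svd(p, full_matrices=False)
            u, v = vt[0], vt[1]
        x = p @ u
        y = p @ v
        return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)

    def resample(self, n: int) -> np.ndarray:
        """Arc-length resampling to n points (closed, no duplicate endpoint)."""
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        target = np.linspace(0.0, total, n, endpoint=False)
        out = np.empty((n, 3))
        for k in range(3):
            out[:, k] = np.interp(target, s, pts[:, k])
        return out


@dataclass
class BezierProfile:
    """Scalar scale profile s(t) for the loft, t in [0,1], Bernstein form.

    End control values must equal 1 so the end cross-sections mate with the
    bone exactly; s must stay positive.
    """

    control_values: list[float] = field(default_factory=lambda: [1.0, 1.0])

    def __post_init__(self):
        c = np.asarray(self.control_values, dtype=float)
        if len(c) < 2:
            raise ValueError("profile needs at least 2 control values")
        if abs(c[0] - 1.0) > 1e-9 or abs(c[-1] - 1.0) > 1e-9:
            raise ValueError("profile end control values must be 1 "
                             "(end sections must match the bone)")
        t = np.linspace(0, 1, 101)
        if np.any(self(t) <= 0):
            raise ValueError("profile must be positive on [0, 1]")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        c = np.asarray(self.control_values, dtype=float)
        n = len(c) - 1
        k = np.arange(n + 1)
        bern = comb(n, k)[:, None] * t[None, :] ** k[:, None] \
            * (1 - t[None, :]) ** (n - k)[:, None]
        return (c @ bern).reshape(t.shape)


@dataclass
class GuideCurve:
    """Open polyline steering the loft's centroid path (or a cap's bulge)."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("a guide curve needs at least 2 points")

    def at(self, t):
        """Arc-length parameterised position(s), t in [0,1]."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] == 0:
            return np.repeat(self.points[:1], len(t), axis=0)
        target = t * s[-1]
        out = np.empty((len(t), 3))
        for k in range(3):
            out[:, k] = np.interp(target, s, self.points[:, k])
        return out


# ---------------------------------------------------------------------------
# minor cavity fill
# ---------------------------------------------------------------------------

def minor_cavity_fill(ls: LevelSet, d: float) -> LevelSet:
    """Morphological closing: dilate by d then erode by d.

    Extensive (result contains the input), increasing, and idempotent at
    voxel resolution; crevices narrower than 2d are filled, convex bodies
    are unchanged.
    """
    if d <= 0:
        raise ValueError("closing distance d must be > 0")
    closed = offset(offset(ls, +d), -d)
    # closing contains its input exactly in the continuum; the final union
    # makes that hold voxel-for-voxel despite redistancing error
    from .levelset import boolean

    return boolean("union", closed, ls)


# ---------------------------------------------------------------------------
# plane / mesh intersection curves
# ---------------------------------------------------------------------------

def plane_mesh_intersection(mesh: trimesh.Trimesh, plane: CrossSectionPlane,
                            chain_tol: float | None = None) -> list[ClosedCurve]:
    """Closed intersection curves of a plane with a watertight mesh.

    Segments from the triangle/plane cuts are chained end-to-end with a
    welding tolerance of 1e-6 of the mesh scale (override with
    ``chain_tol``); curves are returned largest enclosed area first.
    """
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=np.asarray(plane.normal), plane_origin=np.asarray(plane.point))
    if len(segments) == 0:
        return []
    scale = float(np.ptp(mesh.bounds, axis=0).max())
    tol = chain_tol if chain_tol is not None else 1e-6 * scale

    pts = segments.reshape(-1, 3)
    keys = np.round(pts / tol).astype(np.int64)
    _, inv = np.unique(keys, axis=0, return_inverse=True)
    nseg = len(segments)
    ends = inv.reshape(nseg, 2)

    # adjacency: node -> list of (segment, other node)
    adj: dict[int, list[tuple[int, int]]] = {}
    for i, (a, b) in enumerate(ends):
        if a == b:
            continue
        adj.setdefault(int(a), []).append((i, int(b)))
        adj.setdefault(int(b), []).append((i, int(a)))

    coord: dict[int, np.ndarray] = {}
    for p, node in zip(pts, inv):
        coord.setdefault(int(node), p)

    used = np.zeros(nseg, dtype=bool)
    curves = []
    for i in range(nseg):
        if used[i]:
            continue
        a, b = int(ends[i, 0]), int(ends[i, 1])
        if a == b:
            used[i] = True
            continue
        loop = [a, b]
        used[i] = True
        node = b
        closed = False
        while True:
            nxt = None
            for sj, other in adj.get(node, []):
                if not used[sj]:
                    nxt = (sj, other)
                    break
            if nxt is None:
                break
            used[nxt[0]] = True
            node = nxt[1]
            if node == loop[0]:
                closed = True
                break
            loop.append(node)
        if closed and len(loop) >= 3:
            curves.append(ClosedCurve(np.array([coord[n] for n in loop]), plane=plane))

    curves.sort(key=lambda c: c.enclosed_area(), reverse=True)
    return curves


def _outermost_curve(mesh, plane, label: str) -> ClosedCurve:
    curves = plane_mesh_intersection(mesh, plane)
    if not curves:
        raise ValueError(f"{label} does not intersect the defect mesh")
    if len(curves) > 1:
        warnings.warn(f"{label} cuts {len(curves)} closed curves; "
                      "using the largest-area (outer) one")
    return curves[0]


# ---------------------------------------------------------------------------
# segmental fill
# ---------------------------------------------------------------------------

def _align_rings(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cyclically shift / reverse the centered ring B to best match A
    (minimum sum of squared point distances), removing loft twist."""
    best = None
    best_cost = np.inf
    for cand in (B, B[::-1].copy()):
        # cost(s) = const - 2 * sum_j A_j . cand_{j+s}
        dots = np.array([np.sum(A * np.roll(cand, -s, axis=0)) for s in range(len(A))])
        s = int(np.argmax(dots))
        cost = np.sum((A - np.roll(cand, -s, axis=0)) ** 2)
        if cost < best_cost:
            best_cost = cost
            best = np.roll(cand, -s, axis=0)
    return best


def segmental_fill(defect: trimesh.Trimesh,
                   plane_a: CrossSectionPlane,
                   plane_b: CrossSectionPlane,
                   profile: BezierProfile | None = None,
                   guide: GuideCurve | None = None,
                   n_sections: int = 32,
                   h: float = 0.5,
                   band_width: int = DEFAULT_BAND,
                   snap_tol: float = 5.0) -> LevelSet:
    """Bridge a segmental defect between two cross-section planes.

    The outer boundary curves at the two planes are resampled to a common
    point count, correspondence-aligned, and blended linearly; each
    intermediate section is scaled by the Bezier profile about its centroid
    and placed on the centroid path (straight, or the guide curve).  The
    loft is capped at the two planar sections and voxelised.
    """
    if profile is None:
        profile = BezierProfile()
    ca_curve = _outermost_curve(defect, plane_a, "plane A")
    cb_curve = _outermost_curve(defect, plane_b, "plane B")

    peri = max(ca_curve.perimeter(), cb_curve.perimeter())
    n_pts = int(max(64, np.ceil(peri / h)))

    A = ca_curve.resample(n_pts)
    Bp = cb_curve.resample(n_pts)
    cA = A.mean(axis=0)
    cB = Bp.mean(axis=0)
    A0 = A - cA
    B0 = _align_rings(A0, Bp - cB)

    if guide is not None:
        g0 = guide.at(np.array([0.0]))[0]
        g1 = guide.at(np.array([1.0]))[0]
        if np.linalg.norm(g0 - cA) > snap_tol and np.linalg.norm(g0 - cB) > snap_tol:
            raise ValueError("guide curve start is beyond the snap distance "
                             "of both section centroids")
        if np.linalg.norm(g1 - cA) > snap_tol and np.linalg.norm(g1 - cB) > snap_tol:
            raise ValueError("guide curve end is beyond the snap distance "
                             "of both section centroids")
        # orient the guide from A to B
        if np.linalg.norm(g0 - cB) < np.linalg.norm(g0 - cA):
            guide = GuideCurve(guide.points[::-1].copy())
            g0, g1 = g1, g0

    ts = np.linspace(0.0, 1.0, n_sections + 2)
    scale = profile(ts)

    if guide is not None:
        path = guide.at(ts)
        # pin the path endpoints to the section centroids
        path = path + np.outer(1 - ts, cA - path[0]) + np.outer(ts, cB - path[-1])
    else:
        path = np.outer(1 - ts, cA) + np.outer(ts, cB)

    rings = []
    for i, t in enumerate(ts):
        ring = ((1 - t) * A0 + t * B0) * scale[i] + path[i]
        rings.append(ring)

    mesh = _loft_mesh(rings)
    bounds_lo = np.min([r.min(axis=0) for r in rings], axis=0)
    bounds_hi = np.max([r.max(axis=0) for r in rings], axis=0)
    return mesh_to_levelset(mesh, h=h, band_width=band_width,
                            bounds=(bounds_lo, bounds_hi))


def _loft_mesh(rings: list[np.ndarray]) -> trimesh.Trimesh:
    """Closed loft: side wall between consecutive rings, fan caps at ends."""
    n = len(rings[0])
    m = len(rings)
    verts = np.concatenate(rings, axis=0)
    faces = []
    for i in range(m - 1):
        base0 = i * n
        base1 = (i + 1) * n
        j = np.arange(n)
        jn = (j + 1) % n
        faces.append(np.stack([base0 + j, base0 + jn, base1 + j], axis=1))
        faces.append(np.stack([base0 + jn, base1 + jn, base1 + j], axis=1))
    # caps: fan to ring centroid
    c0 = len(verts)
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    j = np.arange(n)
    jn = (j + 1) % n
    faces.append(np.stack([np.full(n, c0), jn, j], axis=1))
    base = (m - 1) * n
    faces.append(np.stack([np.full(n, c0 + 1), base + j, base + jn], axis=1))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.concatenate(faces), process=False)
    mesh.merge_vertices()
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# guided cavity fill (one-sided pockets)
# ---------------------------------------------------------------------------

def guided_cavity_fill(defect: trimesh.Trimesh,
                       opening_plane: CrossSectionPlane,
                       guides: list[GuideCurve] | None = None,
                       h: float = 0.5,
                       band_width: int = DEFAULT_BAND,
                       depth: float | None = None) -> LevelSet:
    """Close a one-sided (non-through) cavity and return the enclosed void.

    The opening boundary curve is capped: flat on the opening plane by
    default, or lifted outward into a cone whose apex height is the largest
    guide-curve elevation above the plane.  The fill is the void between
    the cap and the bone surface, connected to the opening.
    """
    curves = plane_mesh_intersection(defect, opening_plane)
    if not curves:
        raise ValueError("opening plane does not intersect the defect mesh")
    # the cavity mouth is the smallest loop that encloses void (its centroid
    # is not inside the bone); a plane cutting the surrounding bone also
    # yields the bone outline, which is not the mouth
    void = [c for c in curves
            if not _raster.point_in_mesh(c.centroid[None, :], defect.vertices,
                                         defect.faces)[0]]
    loop = min(void, key=lambda c: c.enclosed_area()) if void else curves[0]
    n = np.asarray(opening_plane.normal)
    p0 = np.asarray(opening_plane.point)
    centroid = loop.centroid

    # which side of the plane holds the cavity: the direction along which a
    # ray from the mouth centroid hits the bone
    hits = {}
    for sgn in (+1.0, -1.0):
        t = _raster.ray_hits(centroid + sgn * n * 1e-6, sgn * n,
                             np.asarray(defect.vertices), np.asarray(defect.faces))
        if len(t):
            hits[sgn] = float(t.max())
    if hits:
        sgn = max(hits, key=hits.get)
        a = sgn * n  # unit vector from the plane into the cavity
        depth = (hits[sgn] + 2 * h) if depth is None else depth
    elif depth is not None:
        # through-hole plug: the mouth ray exits without hitting bone, the
        # caller bounds the plug depth explicitly
        a = -n
    else:
        raise ValueError("opening plane does not face a cavity of the mesh "
                         "(give an explicit depth for a through-hole)")

    lift = 0.0
    if guides:
        for g in guides:
            w = (g.points - p0) @ (-a)
            lift = max(lift, float(w.max()))

    u, v = opening_plane.basis()
    # bound the polygon size: finely chained loops (from marching-cubes
    # meshes) would make the in-plane distance field needlessly expensive
    if len(loop.points) > 256:
        loop = ClosedCurve(loop.resample(256), plane=loop.plane)
    poly = np.stack([(loop.points - p0) @ u, (loop.points - p0) @ v], axis=1)

    lo = loop.points.min(axis=0) - (lift + 2 * h)
    hi = loop.points.max(axis=0) + (lift + 2 * h)
    lo = np.minimum(lo, lo + a * 0)  # keep explicit
    lo3 = np.minimum(lo, centroid + a * depth - 2 * h)
    hi3 = np.maximum(hi, centroid + a * depth + 2 * h)
    grid = grid_from_bounds(lo3, hi3, h, band_width)
    defect_ls = mesh_to_levelset(defect, h=h, band_width=band_width,
                                 bounds=(np.asarray(grid.origin), grid.top))

    ax = grid.axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    rel = np.stack([X - p0[0], Y - p0[1], Z - p0[2]], axis=-1)
    U = rel @ u
    V = rel @ v
    W = rel @ a  # positive into the cavity

    # signed 2D distance to the opening polygon
    pts2 = np.stack([U.ravel(), V.ravel()], axis=1)
    seg_a = np.concatenate([poly, np.zeros((len(poly), 1))], axis=1)
    seg_b = np.roll(seg_a, -1, axis=0)
    d2 = _raster.segments_point_distance(
        np.concatenate([pts2, np.zeros((len(pts2), 1))], axis=1), seg_a, seg_b)
    inside2 = _point_in_polygon(pts2, poly)
    sd2 = np.where(inside2, -d2, d2).reshape(U.shape)

    if lift > 0:
        bmax = max(float((-sd2[inside2.reshape(U.shape)]).max()), h)
        eta = lift * np.clip(-sd2, 0.0, None) / bmax
    else:
        eta = np.zeros_like(W)
    w_sdf = np.maximum(-(W + eta), W - depth)
    prism_phi = np.maximum(sd2, w_sdf).astype(np.float32)

    B = np.float32(grid.band)
    fill_phi = np.maximum(prism_phi, -defect_ls.values)
    ind = fill_phi < 0
    kept = np.zeros_like(ind)
    if ind.any():
        labels, nlab = ndi.label(ind)
        keep = np.zeros(nlab + 1, dtype=bool)
        mouth = ind & (np.abs(W) <= 1.5 * h + eta)
        keep[np.unique(labels[mouth])] = True
        keep[0] = False
        kept = keep[labels] & ind
    # suppress voxels (and their sub-voxel boundary fractions) that are not
    # part of a mouth-connected void component: coincident CSG surfaces
    # otherwise leave a phantom half-voxel skin
    halo = ndi.binary_dilation(kept, iterations=2)
    fill_phi = np.where(halo, fill_phi, np.maximum(fill_phi, np.float32(h)))
    return LevelSet(grid, np.clip(fill_phi, -B, B))


def _point_in_polygon(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorised even-odd rule point-in-polygon test."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < np.where(cond, xcross, np.inf))
    return inside
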