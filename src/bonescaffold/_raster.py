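"""Low-level triangle-mesh rasterisation helpers.

Everything here works in *index space*: voxel centers sit at integer
coordinates (i, j, k) and the caller is responsible for mapping world
coordinates to that frame.  The main entry points are

``parity_fill``
    watertight inside/outside classification by counting ray crossings
    along z columns, and

``point_triangle_distance``
    exact vectorised point-to-triangle distances used to refine the
    signed-distance field near the zero crossing.
"""

from __future__ import annotations

import numpy as np

# Deterministic sub-voxel jitter applied to column coordinates so that
# crossings through triangle edges/vertices (measure-zero, but common on
# structured meshes) never land exactly on a column.
_JITTER = (2.3620689655e-4, 1.7241379310e-4)


def parity_fill(vertices: np.ndarray, faces: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Classify voxel centers (integer grid points) as inside a closed mesh.

    Parameters
    ----------
    vertices : (V, 3) float array in index space.
    faces : (F, 3) int array.
    shape : grid shape (nx, ny, nz); voxel centers at 0..n-1 per axis.

    Returns
    -------
    (nx, ny, nz) bool array, True where the center is inside.
    """
    nx, ny, nz = shape
    tri = vertices[faces]  # (F, 3, 3)
    # crossing counts accumulated at the first voxel index above each crossing
    cross = np.zeros((nx, ny, nz + 1), dtype=np.int32)

    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    # 2D projected edges for the barycentric point-in-triangle test
    d1 = v1[:, :2] - v0[:, :2]
    d2 = v2[:, :2] - v0[:, :2]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]

    jx, jy = _JITTER
    for f in range(len(tri)):
        if det[f] == 0.0:  # vertical triangle: no z crossing
            continue
        a, b, c = v0[f], v1[f], v2[f]
        xlo = max(int(np.ceil(min(a[0], b[0], c[0]) - jx)), 0)
        xhi = min(int(np.floor(max(a[0], b[0], c[0]) - jx)), nx - 1)
        ylo = max(int(np.ceil(min(a[1], b[1], c[1]) - jy)), 0)
        yhi = min(int(np.floor(max(a[1], b[1], c[1]) - jy)), ny - 1)
        if xhi < xlo or yhi < ylo:
            continue
        xs = np.arange(xlo, xhi + 1, dtype=np.float64) + jx
        ys = np.arange(ylo, yhi + 1, dtype=np.float64) + jy
        px = xs[:, None] - a[0]
        py = ys[None, :] - a[1]
        inv = 1.0 / det[f]
        u = (px * d2[f, 1] - py * d2[f, 0]) * inv
        v = (py * d1[f, 0] - px * d1[f, 1]) * inv
        hit = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not hit.any():
            continue
        z = a[2] + u * (b[2] - a[2]) + v * (c[2] - a[2])
        ii, jj = np.nonzero(hit)
        zc = z[ii, jj]
        # crossing at height z affects all voxel centers with k > z
        kk = np.floor(zc).astype(np.int64) + 1
        kk = np.clip(kk, 0, nz)
        np.add.at(cross, (ii + xlo, jj + ylo, kk), 1)

    inside = (np.cumsum(cross[:, :, :-1], axis=2) % 2).astype(bool)
    return inside


def sample_surface(vertices: np.ndarray, faces: np.ndarray, spacing: float) -> np.ndarray:
    """Sample points on a triangle soup at roughly ``spacing`` between samples.

    Uses a regular barycentric grid per triangle (deterministic), always
    including the three corners.
    """
    tri = vertices[faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = b - a, c - a
    # characteristic edge length per triangle
    L = np.maximum(np.linalg.norm(e1, axis=1), np.linalg.norm(e2, axis=1))
    L = np.maximum(L, np.linalg.norm(c - b, axis=1))
    nsub = np.maximum(1, np.ceil(L / spacing).astype(int))
    out = [vertices]
    for n in np.unique(nsub):
        sel = nsub == n
        if n == 1:
            # centroid is enough for tiny triangles
            out.append((a[sel] + b[sel] + c[sel]) / 3.0)
            continue
        us = []
        for i in range(n + 1):
            for j in range(n + 1 - i):
                us.append((i / n, j / n))
        us = np.asarray(us)
        pts = (
            a[sel][:, None, :]
            + us[None, :, 0:1] * e1[sel][:, None, :]
            + us[None, :, 1:2] * e2[sel][:, None, :]
        )
        out.append(pts.reshape(-1, 3))
    return np.concatenate(out, axis=0)


def point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from each point to its paired triangle.

    Parameters
    ----------
    points : (N, 3)
    tri : (N, 3, 3) one triangle per point.

    Returns
    -------
    (N,) distances.

    Closest-point-on-triangle via the region classification of the
    standard barycentric clamp (Ericson, Real-Time Collision Detection).
    """
    p = points
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    t = np.where(denom != 0, d1 / np.where(denom == 0, 1.0, denom), 0.0)
    closest[m] = a[m] + t[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    t = np.where(denom != 0, d2 / np.where(denom == 0, 1.0, denom), 0.0)
    closest[m] = a[m] + t[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    closest[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    return np.linalg.norm(p - closest, axis=1)


def ray_hits(origin: np.ndarray, direction: np.ndarray, vertices: np.ndarray,
             faces: np.ndarray) -> np.ndarray:
    """Sorted positive ray parameters t where origin + t*direction crosses
    the triangle soup (Moller-Trumbore, brute force over faces)."""
    tri = vertices[faces]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    d = np.asarray(direction, dtype=float)
    o = np.asarray(origin, dtype=float)
    e1 = v1 - v0
    e2 = v2 - v0
    pv = np.cross(d[None, :], e2)
    det = np.einsum("ij,ij->i", e1, pv)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), 0.0)
    tv = o[None, :] - v0
    u = np.einsum("ij,ij->i", tv, pv) * inv
    qv = np.cross(tv, e1)
    v = np.einsum("ij,j->i", qv, d) * inv
    t = np.einsum("ij,ij->i", e2, qv) * inv
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
    return np.sort(t[hit])


def point_in_mesh(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Containment by crossing parity along +z (points away from mesh edges
    in measure; adequate for generic queries)."""
    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        t = ray_hits(p, np.array([0.0, 0.0, 1.0]), vertices, faces)
        out[i] = (len(t) % 2) == 1
    return out


def segments_point_distance(points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray,
                            chunk: int = 2_000_000) -> np.ndarray:
    """Minimum distance from each point to a set of segments.

    points (N,3); seg_a/seg_b (S,3).  Memory-bounded by chunking points.
    """
    ab = seg_b - seg_a  # (S,3)
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    out = np.empty(len(points), dtype=np.float32)
    step = max(1, chunk // max(1, len(seg_a)))
    for s in range(0, len(points), step):
        p = points[s:s + step]
        ap = p[:, None, :] - seg_a[None, :, :]  # (n,S,3)
        t = np.clip(np.einsum("nsj,sj->ns", ap, ab) / denom[None, :], 0.0, 1.0)
        d = ap - t[:, :, None] * ab[None, :, :]
        out[s:s + step] = np.sqrt(np.einsum("nsj,nsj->ns", d, d).min(axis=1))
    return out
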