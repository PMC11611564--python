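"""Mesh import/export and 3D-printability validation.

Coordinates are millimetres and are preserved exactly on read and write
(no recentering or unit scaling): the scaffold meshes must stay in the
patient frame of the CT segmentation so the DICOM overlay needs no
registration step.

The printability report counts the mesh defects that make a file
unsliceable or ambiguous for additive manufacturing: naked (boundary)
edges, non-manifold edges, self-intersecting face pairs, duplicated and
degenerate faces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

DEGENERATE_AREA_EPS = 1e-10  # mm^2; far below h^2 for any practical voxel size

_FORMATS = {".stl": "stl", ".obj": "obj", ".ply": "ply"}


@dataclass
class MeshQualityReport:
    """Printability check counts; a printable mesh is all zeros and watertight."""

    non_manifold_edges: int
    naked_edges: int
    self_intersecting_faces: int
    duplicated_faces: int
    degenerate_faces: int
    watertight: bool

    @property
    def passed(self) -> bool:
        return (
            self.watertight
            and self.non_manifold_edges == 0
            and self.naked_edges == 0
            and self.self_intersecting_faces == 0
            and self.duplicated_faces == 0
            and self.degenerate_faces == 0
        )

    def as_dict(self) -> dict:
        return {
            "non_manifold_edges": self.non_manifold_edges,
            "naked_edges": self.naked_edges,
            "self_intersecting_faces": self.self_intersecting_faces,
            "duplicated_faces": self.duplicated_faces,
            "degenerate_faces": self.degenerate_faces,
            "watertight": self.watertight,
            "passed": self.passed,
        }


def _format_for(path, format: str | None) -> str:
    if format is not None:
        f = format.lower()
        if f not in ("stl", "obj", "ply"):
            raise ValueError(f"unsupported mesh format {format!r}")
        return f
    suffix = Path(path).suffix.lower()
    if suffix not in _FORMATS:
        raise ValueError(f"cannot infer mesh format from {path!r}")
    return _FORMATS[suffix]


def read_mesh(path, format: str | None = None) -> trimesh.Trimesh:
    """Read an STL/OBJ/PLY surface mesh, coordinates preserved exactly."""
    fmt = _format_for(path, format)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # parse errors surface with the file named
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"{path}: no triangle geometry found")
    # weld coincident vertices (STL stores a triangle soup); coordinates are
    # untouched, only shared-vertex topology is restored
    mesh.merge_vertices()
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path, format: str | None = None) -> None:
    """Write a mesh (binary STL by default), coordinates unchanged."""
    if mesh is None or len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    fmt = _format_for(path, format)
    mesh.export(str(path), file_type=fmt)


def _edge_counts(faces: np.ndarray) -> np.ndarray:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return counts


def check_printability(mesh: trimesh.Trimesh, check_self_intersections: bool = True
                       ) -> MeshQualityReport:
    """Run all printability checks; never modifies the input.

    Definitions: naked edge = exactly one incident face; non-manifold edge
    = three or more; degenerate face = repeated vertex index or area below
    ``DEGENERATE_AREA_EPS``; duplicated face = same vertex triple regardless
    of orientation; self-intersection = a proper (non-coplanar) crossing
    between two triangles sharing no vertex index.
    """
    faces = np.asarray(mesh.faces)
    verts = np.asarray(mesh.vertices, dtype=np.float64)

    counts = _edge_counts(faces)
    naked = int((counts == 1).sum())
    nonmanifold = int((counts >= 3).sum())

    repeated = (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) \
        | (faces[:, 0] == faces[:, 2])
    tri = verts[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    degenerate = int((repeated | (areas < DEGENERATE_AREA_EPS)).sum())

    keys = np.sort(faces, axis=1)
    _, inv, kcounts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    duplicated = int((kcounts[inv] > 1).sum())

    if check_self_intersections:
        selfint = _count_self_intersections(verts, faces)
    else:
        selfint = 0

    return MeshQualityReport(
        non_manifold_edges=nonmanifold,
        naked_edges=naked,
        self_intersecting_faces=selfint,
        duplicated_faces=duplicated,
        degenerate_faces=degenerate,
        watertight=(naked == 0),
    )


def _count_self_intersections(verts: np.ndarray, faces: np.ndarray) -> int:
    """Number of faces involved in a proper pairwise intersection.

    Candidate pairs come from a KD-tree on face centroids with radius twice
    the largest face circumradius; each candidate pair is tested by the
    nine segment-triangle crossings (edges of A against B and vice versa).
    Coplanar overlaps without an edge crossing are not counted (they are
    caught by the duplicated-face check in the common case).
    """
    if len(faces) < 2:
        return 0
    tri = verts[faces]
    centroids = tri.mean(axis=1)
    radii = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    rmax = float(radii.max())
    if rmax == 0:
        return 0
    pairs = cKDTree(centroids).query_pairs(r=2.0 * rmax, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    # drop pairs sharing any vertex index (mesh adjacency, not a defect)
    fa = faces[pairs[:, 0]]
    fb = faces[pairs[:, 1]]
    share = (fa[:, :, None] == fb[:, None, :]).any(axis=(1, 2))
    pairs = pairs[~share]
    if len(pairs) == 0:
        return 0

    bad = np.zeros(len(pairs), dtype=bool)
    A = tri[pairs[:, 0]]
    B = tri[pairs[:, 1]]
    for src, dst in ((A, B), (B, A)):
        for e in range(3):
            p = src[:, e]
            q = src[:, (e + 1) % 3]
            bad |= _segment_hits_triangle(p, q, dst)
    flagged = np.unique(np.concatenate([pairs[bad, 0], pairs[bad, 1]]))
    return int(len(flagged))


def _segment_hits_triangle(p: np.ndarray, q: np.ndarray, tri: np.ndarray,
                           eps: float = 1e-12) -> np.ndarray:
    """Vectorised Moller-Trumbore: does segment pq properly cross triangle?"""
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    d = q - p
    e1 = v1 - v0
    e2 = v2 - v0
    pv = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pv)
    scale = np.maximum(np.einsum("ij,ij->i", e1, e1), 1e-300)
    ok = np.abs(det) > eps * scale
    inv = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), 0.0)
    tv = p - v0
    u = np.einsum("ij,ij->i", tv, pv) * inv
    qv = np.cross(tv, e1)
    v = np.einsum("ij,ij->i", d, qv) * inv
    t = np.einsum("ij,ij->i", e2, qv) * inv
    tol = 1e-9
    return (ok & (u > tol) & (v > tol) & (u + v < 1 - tol)
            & (t > tol) & (t < 1 - tol))
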