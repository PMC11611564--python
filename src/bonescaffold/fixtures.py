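"""Synthetic geometry and synthetic CT emulating clinical inputs.

No patient data ships with or is needed by this package: these generators
produce watertight defect meshes at adult-long-bone scale (plus hardware
and CT stacks) shaped like the three clinical situations the pipeline
serves — a segmental diaphyseal gap, a shaft with narrow surface crevices,
and a curved cranial plate with a through-hole — so the entire design
workflow can be exercised and validated end to end.

Default dimensions: cortical tube outer radius 15 mm, wall 6 mm, length
120 mm, mid-shaft gap 40 mm; at the workflow's default voxel size these
give clinical-scale voxel counts that stay desk-sized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .dicom_overlay import DicomVolume, scaffold_mask
from .levelset import from_sdf, levelset_to_mesh

__all__ = ["FixtureSpec", "make_defect_mesh", "make_synthetic_ct"]

_KINDS = ("segmental_tube", "notched_tube", "cranial_plate", "hardware_rod_plate")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic defect; lengths in mm."""

    kind: str = "segmental_tube"
    outer_radius: float = 15.0
    inner_radius: float = 9.0
    length: float = 120.0
    gap_length: float = 40.0
    notch_width: float = 1.0
    notch_depth: float = 3.0
    notch_length: float = 10.0
    n_notches: int = 4
    plate_radius: float = 60.0  # curvature radius of the cranial shell
    plate_thickness: float = 5.0
    hole_radius: float = 10.0
    rod_radius: float = 4.0
    screw_radius: float = 2.0
    screw_count: int = 4
    mesh_h: float = 0.5  # resolution for implicitly generated meshes
    rng_seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if min(self.outer_radius, self.inner_radius, self.length) <= 0:
            raise ValueError("all lengths must be > 0")
        if self.inner_radius >= self.outer_radius:
            raise ValueError("inner radius must be < outer radius")
        if self.gap_length >= self.length:
            raise ValueError("gap length must be < tube length")


# ---------------------------------------------------------------------------
# exact hollow-tube meshes
# ---------------------------------------------------------------------------

def _tube_segment_mesh(z0: float, z1: float, r_out: float, r_in: float,
                       sections: int = 96, max_edge: float = 3.0) -> trimesh.Trimesh:
    """Watertight hollow cylinder [z0, z1], triangle size bounded by
    ``max_edge`` (axially subdivided walls, radially subdivided caps)."""
    theta = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    cos, sin = np.cos(theta), np.sin(theta)
    nz = max(2, int(np.ceil((z1 - z0) / max_edge)) + 1)
    zs = np.linspace(z0, z1, nz)
    nr = max(2, int(np.ceil((r_out - r_in) / max_edge)) + 1)
    rs = np.linspace(r_in, r_out, nr)

    verts = []
    ring_index = {}

    def ring(r, z):
        key = (round(r, 9), round(z, 9))
        if key not in ring_index:
            base = len(verts) * 1
            start = sum(len(v) for v in verts)
            verts.append(np.stack([r * cos, r * sin, np.full_like(cos, z)], axis=1))
            ring_index[key] = start
        return ring_index[key]

    faces = []

    def strip(i0, i1, flip=False):
        j = np.arange(sections)
        jn = (j + 1) % sections
        f1 = np.stack([i0 + j, i0 + jn, i1 + j], axis=1)
        f2 = np.stack([i0 + jn, i1 + jn, i1 + j], axis=1)
        f = np.concatenate([f1, f2])
        if flip:
            f = f[:, ::-1]
        faces.append(f)

    # outer wall (normals out): ascending z
    for k in range(nz - 1):
        strip(ring(r_out, zs[k]), ring(r_out, zs[k + 1]))
    # inner wall (normals inward toward axis = outward of solid): flipped
    for k in range(nz - 1):
        strip(ring(r_in, zs[k]), ring(r_in, zs[k + 1]), flip=True)
    # bottom cap (normal -z): annulus rings at z0
    for k in range(nr - 1):
        strip(ring(rs[k], z0), ring(rs[k + 1], z0))
    # top cap (normal +z): flipped
    for k in range(nr - 1):
        strip(ring(rs[k], z1), ring(rs[k + 1], z1), flip=True)

    mesh = trimesh.Trimesh(vertices=np.concatenate(verts),
                           faces=np.concatenate(faces), process=False)
    mesh.merge_vertices()
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# implicit helpers for sculpted fixtures
# ---------------------------------------------------------------------------

def _sdf_tube(r_out, r_in, z0, z1):
    def f(X, Y, Z):
        r = np.sqrt(X**2 + Y**2)
        dz = np.maximum(z0 - Z, Z - z1)
        solid = np.maximum(r - r_out, dz)
        return np.maximum(solid, r_in - r)
    return f


def _sdf_rot_box(angle, center_r, half_w, half_d, z0, z1):
    """Box radially oriented at polar angle: half_d radial, half_w tangential."""
    ca, sa = np.cos(angle), np.sin(angle)

    def f(X, Y, Z):
        # rotate into the notch frame: u radial, v tangential
        u = X * ca + Y * sa - center_r
        v = -X * sa + Y * ca
        qu = np.abs(u) - half_d
        qv = np.abs(v) - half_w
        qz = np.maximum(z0 - Z, Z - z1)
        outside = np.sqrt(np.maximum(qu, 0)**2 + np.maximum(qv, 0)**2
                          + np.maximum(qz, 0)**2)
        return outside + np.minimum(np.maximum(qu, np.maximum(qv, qz)), 0.0)
    return f


# ---------------------------------------------------------------------------
# defect meshes
# ---------------------------------------------------------------------------

def make_defect_mesh(spec: FixtureSpec) -> trimesh.Trimesh:
    """Watertight synthetic defect (or hardware) mesh for the given spec."""
    if spec.kind == "segmental_tube":
        seg = (spec.length - spec.gap_length) / 2.0
        lower = _tube_segment_mesh(0.0, seg, spec.outer_radius, spec.inner_radius)
        upper = _tube_segment_mesh(spec.length - seg, spec.length,
                                   spec.outer_radius, spec.inner_radius)
        return trimesh.util.concatenate([lower, upper])

    if spec.kind == "notched_tube":
        tube = _sdf_tube(spec.outer_radius, spec.inner_radius, 0.0, spec.length)
        zmid = spec.length / 2.0
        notches = [
            _sdf_rot_box(
                angle=2 * np.pi * i / spec.n_notches,
                center_r=spec.outer_radius,
                half_w=spec.notch_width / 2.0,
                half_d=spec.notch_depth,
                z0=zmid - spec.notch_length / 2.0,
                z1=zmid + spec.notch_length / 2.0,
            )
            for i in range(spec.n_notches)
        ]

        def sdf(X, Y, Z):
            v = tube(X, Y, Z)
            for n in notches:
                v = np.maximum(v, -n(X, Y, Z))
            return v

        R = spec.outer_radius
        ls = from_sdf(sdf, ([-R, -R, 0.0], [R, R, spec.length]), spec.mesh_h)
        return levelset_to_mesh(ls)

    if spec.kind == "cranial_plate":
        R = spec.plate_radius
        t = spec.plate_thickness
        cap_z = 0.75 * R  # shell kept above this height: a skull-cap patch

        def sdf(X, Y, Z):
            rad = np.sqrt(X**2 + Y**2 + Z**2)
            shell = np.abs(rad - R) - t / 2.0
            capped = np.maximum(shell, cap_z - Z)
            rxy = np.sqrt(X**2 + Y**2)
            hole = np.maximum(rxy - spec.hole_radius, np.abs(Z - R) - R)
            return np.maximum(capped, -hole)

        rmax = np.sqrt(max(R**2 - cap_z**2, 0.0)) + t
        ls = from_sdf(sdf, ([-rmax, -rmax, cap_z - t], [rmax, rmax, R + t]),
                      spec.mesh_h)
        return levelset_to_mesh(ls)

    if spec.kind == "hardware_rod_plate":
        # intramedullary rod spanning the gap plus a lateral plate with screws
        rod_len = spec.gap_length + 40.0
        z0 = (spec.length - rod_len) / 2.0
        rr = spec.rod_radius
        plate_x = spec.outer_radius + 2.0

        def sdf(X, Y, Z):
            r = np.sqrt(X**2 + Y**2)
            rod = np.maximum(r - rr, np.maximum(z0 - Z, Z - (z0 + rod_len)))
            qx = np.abs(X - plate_x) - 1.5
            qy = np.abs(Y) - 6.0
            qz = np.abs(Z - spec.length / 2.0) - rod_len / 2.0
            plate = np.maximum(qx, np.maximum(qy, qz))
            v = np.minimum(rod, plate)
            zs = np.linspace(spec.length / 2.0 - rod_len / 2.0 + 8.0,
                             spec.length / 2.0 + rod_len / 2.0 - 8.0,
                             spec.screw_count)
            for zc in zs:
                ry = np.sqrt(Y**2 + (Z - zc)**2)
                screw = np.maximum(ry - spec.screw_radius,
                                   np.maximum(spec.outer_radius - 12.0 - X,
                                              X - (plate_x + 1.5)))
                v = np.minimum(v, screw)
            return v

        lim = plate_x + 4.0
        ls = from_sdf(sdf, ([-lim, -10, z0 - 2], [lim, 10, z0 + rod_len + 2]),
                      spec.mesh_h)
        return levelset_to_mesh(ls)

    raise ValueError(f"unknown fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# synthetic CT
# ---------------------------------------------------------------------------

def make_synthetic_ct(defect: trimesh.Trimesh,
                      hardware: trimesh.Trimesh | None = None,
                      spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                      intensities: tuple[int, int, int, int] = (-1000, 40, 700, 3000),
                      noise_sd: float = 0.0,
                      rng_seed: int = 0,
                      soft_margin: float = 10.0) -> DicomVolume:
    """Labelled CT stack around the defect: air / soft tissue / bone / metal.

    Soft tissue fills a padded box around the geometry; bone is the defect
    mesh interior, metal the hardware interior (precedence metal > bone >
    soft > air).  Optional Gaussian noise (integer-rounded) with a fixed
    seed keeps volumes reproducible.
    """
    air, soft, bone, metal = intensities
    meshes = [defect] + ([hardware] if hardware is not None else [])
    lo = np.min([m.bounds[0] for m in meshes], axis=0) - soft_margin - 2
    hi = np.max([m.bounds[1] for m in meshes], axis=0) + soft_margin + 2
    sp = np.asarray([spacing[1], spacing[0], spacing[2]])  # x≈col, y≈row, z≈slice
    shape_world = np.ceil((hi - lo) / sp).astype(int) + 1
    # rows index y, columns index x, slices index z (axis-aligned frame)
    shape = (int(shape_world[1]), int(shape_world[0]), int(shape_world[2]))
    vol = DicomVolume(
        intensities=np.full(shape, air, dtype=np.int16),
        spacing=spacing,
        origin=tuple(lo),
        metadata={"RescaleSlope": 1.0, "RescaleIntercept": 0.0},
    )

    # soft-tissue ellipsoid-ish box: everything inside the padded bounds
    # minus the outer 2 mm air rim
    r_idx, c_idx, s_idx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    world_x = lo[0] + c_idx * spacing[1]
    world_y = lo[1] + r_idx * spacing[0]
    world_z = lo[2] + s_idx * spacing[2]
    soft_mask = ((world_x > lo[0] + 2) & (world_x < hi[0] - 2)
                 & (world_y > lo[1] + 2) & (world_y < hi[1] - 2)
                 & (world_z > lo[2] + 2) & (world_z < hi[2] - 2))
    vol.intensities[soft_mask] = soft

    bone_mask = scaffold_mask(vol, [defect])
    vol.intensities[bone_mask] = bone
    if hardware is not None:
        metal_mask = scaffold_mask(vol, [hardware])
        vol.intensities[metal_mask] = metal

    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        noise = rng.normal(0.0, noise_sd, size=shape)
        vol.intensities = np.clip(
            vol.intensities.astype(np.int64) + np.round(noise).astype(np.int64),
            np.iinfo(np.int16).min, np.iinfo(np.int16).max).astype(np.int16)
    return vol
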