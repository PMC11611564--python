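"""Cavity filling: morphological closing, section curves, lofts, cap fills."""

import warnings

import numpy as np
import pytest
import trimesh

from bonescaffold import levelset as lv
from bonescaffold.fill import (
    BezierProfile,
    CrossSectionPlane,
    GuideCurve,
    guided_cavity_fill,
    minor_cavity_fill,
    plane_mesh_intersection,
    segmental_fill,
)

from conftest import common_grid, indicator_on

H = 0.25


@pytest.fixture(scope="module")
def slotted_sphere():
    """Sphere r=5 with a 1 mm wide, 3 mm deep radial slot."""
    s = lv.sphere([0, 0, 0], 5.0, H)
    slot = lv.box([-0.5, -6, 2.0], [0.5, 6, 6.0], H, bounds=([-6, -6, -6], [6, 6, 6]))
    return lv.difference(s, slot), s


class TestMinorCavityFill:
    def test_convex_body_unchanged_within_one_voxel(self):
        s = lv.sphere([0, 0, 0], 5.0, H)
        closed = minor_cavity_fill(s, 1.0)
        grid = common_grid(s, closed)
        sym_diff = indicator_on(s, grid) ^ indicator_on(closed, grid)
        # any changed voxel sits within one voxel of the surface
        vals = lv.to_grid(s, grid).values
        assert np.all(np.abs(vals[sym_diff]) <= 1.5 * H)

    def test_slot_narrower_than_2d_refilled(self, slotted_sphere):
        """The slot (width 1 < 2d) refills except the rounded meniscus where
        its mouth meets the sphere: everything deeper than d is material."""
        slotted, full = slotted_sphere
        closed = minor_cavity_fill(slotted, 1.0)
        removed = full.volume() - slotted.volume()
        refilled = closed.volume() - slotted.volume()
        assert 0.8 * removed <= refilled <= 1.05 * removed
        # all slot voxels deeper than d below the sphere surface are filled
        grid = closed.grid
        ax = grid.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2)
        deep_slot = (np.abs(X) < 0.5 - H) & (Z > 2.0 + H) & (r < 4.0 - H)
        assert np.all(closed.indicator()[deep_slot])

    def test_extensive(self, slotted_sphere):
        slotted, _ = slotted_sphere
        closed = minor_cavity_fill(slotted, 1.0)
        grid = common_grid(slotted, closed)
        assert not np.any(indicator_on(slotted, grid) & ~indicator_on(closed, grid))

    def test_increasing(self, slotted_sphere):
        slotted, full = slotted_sphere
        ca = minor_cavity_fill(slotted, 1.0)
        cb = minor_cavity_fill(full, 1.0)
        grid = common_grid(ca, cb)
        # slotted ⊆ full ⇒ close(slotted) ⊆ close(full)
        assert not np.any(indicator_on(ca, grid) & ~indicator_on(cb, grid))

    def test_idempotent_within_one_voxel(self, slotted_sphere):
        slotted, _ = slotted_sphere
        once = minor_cavity_fill(slotted, 1.0)
        twice = minor_cavity_fill(once, 1.0)
        grid = common_grid(once, twice)
        diff = indicator_on(once, grid) ^ indicator_on(twice, grid)
        vals = lv.to_grid(once, grid).values
        assert np.all(np.abs(vals[diff]) <= 1.5 * H)

    def test_nonpositive_distance_rejected(self, sphere_ls):
        with pytest.raises(ValueError):
            minor_cavity_fill(sphere_ls, 0.0)


class TestPlaneMeshIntersection:
    def test_equatorial_circle_length(self, sphere_mesh):
        pl = CrossSectionPlane((0, 0, 0), (0, 0, 1))
        curves = plane_mesh_intersection(sphere_mesh, pl)
        assert len(curves) == 1
        assert curves[0].perimeter() == pytest.approx(2 * np.pi * 5.0, rel=0.02)

    def test_nonintersecting_plane_empty(self, sphere_mesh):
        pl = CrossSectionPlane((0, 0, 20), (0, 0, 1))
        assert plane_mesh_intersection(sphere_mesh, pl) == []

    def test_hollow_tube_gives_nested_curves(self):
        tub = lv.levelset_to_mesh(lv.tube([0, 0, -5], [0, 0, 1], 5, 3, 10, 0.2))
        pl = CrossSectionPlane((0, 0, 0), (0, 0, 1))
        curves = plane_mesh_intersection(tub, pl)
        assert len(curves) == 2
        # ordered by enclosed area: outer first
        assert curves[0].enclosed_area() > curves[1].enclosed_area()
        assert curves[0].perimeter() == pytest.approx(2 * np.pi * 5, rel=0.03)
        assert curves[1].perimeter() == pytest.approx(2 * np.pi * 3, rel=0.03)


class TestBezierProfile:
    def test_endpoints_must_be_one(self):
        with pytest.raises(ValueError, match="end control"):
            BezierProfile([1.0, 0.5])

    def test_positive_required(self):
        with pytest.raises(ValueError, match="positive"):
            BezierProfile([1.0, -4.0, 1.0])

    def test_waist_value(self):
        prof = BezierProfile([1.0, 0.0, 1.0])
        assert prof(np.array([0.5]))[0] == pytest.approx(0.5)
        assert prof(np.array([0.0]))[0] == pytest.approx(1.0)
        assert prof(np.array([1.0]))[0] == pytest.approx(1.0)


PLANE_A = CrossSectionPlane((0, 0, -5.2), (0, 0, 1))
PLANE_B = CrossSectionPlane((0, 0, 5.2), (0, 0, 1))


class TestSegmentalFill:
    def test_cylinder_volume(self, two_cylinder_defect):
        fill = segmental_fill(two_cylinder_defect, PLANE_A, PLANE_B, h=H)
        assert fill.volume() == pytest.approx(np.pi * 25.0 * 10.4, rel=0.03)

    def test_plane_missing_mesh_rejected(self, two_cylinder_defect):
        bad = CrossSectionPlane((0, 0, 200.0), (0, 0, 1))
        with pytest.raises(ValueError, match="does not intersect"):
            segmental_fill(two_cylinder_defect, bad, PLANE_B, h=H)

    def test_waisted_profile_scales_mid_area(self, two_cylinder_defect):
        prof = BezierProfile([1.0, 0.0, 1.0])
        fill = segmental_fill(two_cylinder_defect, PLANE_A, PLANE_B,
                              profile=prof, h=H)
        mesh = lv.levelset_to_mesh(fill)
        mid = plane_mesh_intersection(mesh, CrossSectionPlane((0, 0, 0), (0, 0, 1)))
        s_mid = prof(np.array([0.5]))[0]
        assert mid[0].enclosed_area() == pytest.approx(
            s_mid**2 * np.pi * 25.0, rel=0.05)

    def test_prism_property_identity_profile(self, two_cylinder_defect):
        """Congruent sections + identity profile: every intermediate
        cross-section stays congruent to the ends (a prism)."""
        fill = segmental_fill(two_cylinder_defect, PLANE_A, PLANE_B, h=H)
        mesh = lv.levelset_to_mesh(fill)
        for z in (-2.5, 0.0, 2.5):
            cur = plane_mesh_intersection(mesh, CrossSectionPlane((0, 0, z), (0, 0, 1)))
            assert cur[0].enclosed_area() == pytest.approx(np.pi * 25.0, rel=0.03)

    def test_guide_curve_steers_centroid_path(self):
        R = 20.0
        ts = np.linspace(0, np.pi / 2, 30)
        gpts = np.stack([R - R * np.cos(ts), np.zeros_like(ts), R * np.sin(ts)],
                        axis=1)
        cA = trimesh.creation.cylinder(
            radius=4, height=8, sections=64,
            transform=trimesh.transformations.translation_matrix([0, 0, -4.0]))
        T = trimesh.transformations.rotation_matrix(np.pi / 2, [0, 1, 0])
        T[:3, 3] = [24.0, 0.0, 20.0]
        cB = trimesh.creation.cylinder(radius=4, height=8, sections=64, transform=T)
        defect = trimesh.util.concatenate([cA, cB])
        pa = CrossSectionPlane((0, 0, -0.5), (0, 0, 1))
        pb = CrossSectionPlane((20.5, 0, 20.0), (1, 0, 0))
        h = 0.4
        fill = segmental_fill(defect, pa, pb, guide=GuideCurve(gpts), h=h,
                              snap_tol=3.0)
        mesh = lv.levelset_to_mesh(fill)
        # mid-arc slice: centroid within one voxel of the guide point
        k = 15
        normal = (np.sin(ts[k]), 0.0, np.cos(ts[k]))
        mid = plane_mesh_intersection(mesh, CrossSectionPlane(tuple(gpts[k]), normal))
        assert np.linalg.norm(mid[0].centroid - gpts[k]) <= 2 * h

    def test_guide_endpoints_snap_enforced(self, two_cylinder_defect):
        g = GuideCurve(np.array([[50.0, 0, -5], [50.0, 0, 5]]))
        with pytest.raises(ValueError, match="snap"):
            segmental_fill(two_cylinder_defect, PLANE_A, PLANE_B, guide=g,
                           h=H, snap_tol=5.0)

    def test_fill_spans_both_sections(self, two_cylinder_defect):
        fill = segmental_fill(two_cylinder_defect, PLANE_A, PLANE_B, h=H)
        lo, hi = fill.interior_bounds()
        assert lo[2] == pytest.approx(-5.2, abs=2 * H)
        assert hi[2] == pytest.approx(5.2, abs=2 * H)


@pytest.fixture(scope="module")
def pocket_slab():
    slab = lv.box([-15, -15, -10], [15, 15, 0], H)
    pocket = lv.sphere([0, 0, 0], 6.0, H, bounds=([-15, -15, -10], [15, 15, 0]))
    solid = lv.difference(slab, pocket)
    return lv.levelset_to_mesh(solid), lv.levelset_to_mesh(slab)


class TestGuidedCavityFill:
    OPENING = CrossSectionPlane((0, 0, -0.1), (0, 0, 1))

    def test_hemispherical_pocket_volume(self, pocket_slab):
        mesh, _ = pocket_slab
        fill = guided_cavity_fill(mesh, self.OPENING, h=H)
        assert fill.volume() == pytest.approx(2 / 3 * np.pi * 216.0, rel=0.05)

    def test_flush_surface_near_empty(self, pocket_slab):
        _, flat = pocket_slab
        fill = guided_cavity_fill(flat, self.OPENING, h=H)
        assert fill.volume() < 5.0

    def test_bulging_guide_increases_volume(self, pocket_slab):
        mesh, _ = pocket_slab
        planar = guided_cavity_fill(mesh, self.OPENING, h=H)
        g = GuideCurve(np.array([[-6, 0, 0], [0, 0, 3.0], [6, 0, 0]]))
        bulged = guided_cavity_fill(mesh, self.OPENING, guides=[g], h=H)
        assert bulged.volume() > planar.volume()

    def test_plane_missing_mesh_rejected(self, pocket_slab):
        mesh, _ = pocket_slab
        with pytest.raises(ValueError, match="does not intersect"):
            guided_cavity_fill(mesh, CrossSectionPlane((0, 0, 50), (0, 0, 1)), h=H)
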