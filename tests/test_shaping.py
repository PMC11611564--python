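"""Insertion sweep, scaffold assembly, splitting, flanges."""

import numpy as np
import pytest

from bonescaffold import levelset as lv
from bonescaffold.fill import CrossSectionPlane
from bonescaffold.shaping import (
    ScaffoldDesign,
    SurgicalApproach,
    add_flanges,
    scaffold_from_fill,
    split_by_planes,
    sweep,
    sweep_steps,
)

from conftest import common_grid, indicator_on

H = 0.5


def brute_force_sweep(ls, direction, length):
    """Oracle: union of translates at every voxel step."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    out = ls.copy()
    n = int(round(length / ls.h))
    for k in range(1, n + 1):
        out = lv.union(out, lv.translate(ls, d * (k * ls.h)))
    return out


class TestSweep:
    def test_zero_length_identity(self):
        b = lv.box([0, 0, 0], [5, 5, 5], H)
        out = sweep(b, [1, 0, 0], 0.0)
        assert np.array_equal(out.values, b.values)

    def test_extent_grows_by_length(self):
        b = lv.box([0, 0, 0], [10, 6, 6], H)
        out = sweep(b, [1, 0, 0], 20.0)
        lo, hi = out.interior_bounds()
        assert (hi[0] - lo[0] + H) == pytest.approx(30.0, abs=H)

    def test_doubling_schedule_step_count(self):
        # ceil(log2(L/h + 1)) unions including the final partial step
        for L, h in ((20.0, 0.5), (7.0, 0.5), (1.0, 0.25), (12.8, 0.4)):
            steps = sweep_steps(L, h)
            assert len(steps) == int(np.ceil(np.log2(L / h + 1)))
            assert sum(steps) == pytest.approx(L)

    @pytest.mark.parametrize("direction", [(1, 0, 0), (0, 1, 0), (0, 0, 1)])
    @pytest.mark.parametrize("length", [3.0, 7.5, 14.0])
    def test_matches_brute_force_oracle(self, direction, length):
        """Indicator-level equality with the per-voxel-step union oracle
        (the fidelity claim of the compounding schedule)."""
        b = lv.box([0, 0, 0], [6, 5, 4], H, bounds=([-2, -2, -2], [8, 7, 6]))
        fast = sweep(b, direction, length)
        slow = brute_force_sweep(b, direction, length)
        grid = common_grid(fast, slow)
        assert np.array_equal(indicator_on(fast, grid), indicator_on(slow, grid))

    def test_extensive_and_monotone(self):
        b = lv.box([0, 0, 0], [6, 6, 6], H)
        s1 = sweep(b, [0, 1, 0], 4.0)
        s2 = sweep(b, [0, 1, 0], 9.0)
        grid = common_grid(s1, s2)
        ib = indicator_on(b, grid)
        i1 = indicator_on(s1, grid)
        i2 = indicator_on(s2, grid)
        assert not np.any(ib & ~i1)
        assert not np.any(i1 & ~i2)


class TestScaffoldFromFill:
    def test_disjoint_obstruction_leaves_fill_untouched(self):
        fill = lv.box([0, 0, 0], [10, 10, 10], H)
        obs = lv.sphere([40, 0, 40], 3.0, H)
        des = scaffold_from_fill(fill, obs, SurgicalApproach((0, 0, 1)),
                                 clearance=0.1)
        grid = common_grid(des.solid, fill)
        assert np.array_equal(indicator_on(des.solid, grid),
                              indicator_on(fill, grid))

    def test_fully_shadowed_fill_errors(self):
        fill = lv.box([0, 0, 0], [10, 10, 10], H)
        obs = lv.box([-1, -1, -10], [11, 11, -1], H)
        with pytest.raises(ValueError, match="shadowed"):
            scaffold_from_fill(fill, obs, SurgicalApproach((0, 0, 1)),
                               clearance=0.1)

    def test_scaffold_avoids_swept_shadow(self):
        fill = lv.box([0, 0, 0], [10, 10, 10], H)
        obs = lv.box([-1, -1, -6], [4, 11, -1], H)
        des = scaffold_from_fill(fill, obs, SurgicalApproach((0, 0, 1)),
                                 clearance=0.1)
        shadow = sweep(obs, [0, 0, 1], des.provenance["sweep_length_mm"])
        grid = common_grid(des.solid, shadow)
        assert not np.any(indicator_on(des.solid, grid)
                          & indicator_on(shadow, grid))

    def test_clearance_gap_on_tube_fixture(self):
        """Min surface distance respects the configured clearance."""
        from bonescaffold.evaluate import min_surface_distance
        from bonescaffold.fill import segmental_fill
        from bonescaffold.fixtures import FixtureSpec, make_defect_mesh

        h = 0.4
        mesh = make_defect_mesh(FixtureSpec(kind="segmental_tube"))
        defect = lv.mesh_to_levelset(mesh, h=h,
                                     bounds=([-17, -17, 30], [17, 17, 90]))
        with pytest.warns(UserWarning):
            fill = segmental_fill(mesh, CrossSectionPlane((0, 0, 37), (0, 0, 1)),
                                  CrossSectionPlane((0, 0, 83), (0, 0, 1)), h=h)
        des = scaffold_from_fill(fill, defect, SurgicalApproach((-1, 0, 0)),
                                 clearance=0.5)
        smesh = lv.levelset_to_mesh(des.solid)
        fc = mesh.triangles_center
        sub = mesh.submesh([np.nonzero((fc[:, 2] > 30) & (fc[:, 2] < 90))[0]],
                           append=True)
        dmin = min_surface_distance(smesh, sub, sample_spacing=h / 2)
        assert dmin >= 0.5 - h


class TestSplitByPlanes:
    def test_no_planes_single_piece(self, sphere_ls):
        pieces = split_by_planes(sphere_ls, [])
        assert len(pieces) == 1
        assert np.array_equal(pieces[0].indicator(), sphere_ls.indicator())

    def test_midplane_splits_cylinder_in_two(self):
        fill = lv.cylinder([0, 0, 0], [0, 0, 1], 5.0, 20.0, H)
        pieces = split_by_planes(fill, [CrossSectionPlane((0, 0, 10), (0, 0, 1))])
        assert len(pieces) == 2
        total = sum(p.volume() for p in pieces)
        assert total == pytest.approx(fill.volume(), rel=0.01)

    def test_partition_exact_at_indicator_level(self):
        fill = lv.cylinder([0, 0, 0], [0, 0, 1], 5.0, 20.0, H)
        planes = [CrossSectionPlane((0, 0, 7), (0, 0, 1)),
                  CrossSectionPlane((0, 0, 13), (0, 0, 1))]
        pieces = split_by_planes(fill, planes)
        assert len(pieces) == 3
        counts = sum(indicator_on(p, fill.grid).astype(int) for p in pieces)
        assert np.array_equal(counts > 0, fill.indicator())
        assert counts.max() == 1  # disjoint

    def test_plane_missing_fill_gives_original(self, sphere_ls):
        pieces = split_by_planes(sphere_ls,
                                 [CrossSectionPlane((0, 0, 50), (0, 0, 1))])
        assert len(pieces) == 1
        assert np.array_equal(pieces[0].indicator(), sphere_ls.indicator())


class TestAddFlanges:
    def _design(self):
        solid = lv.box([0, 0, 0], [10, 10, 4], H)
        return ScaffoldDesign(solid=solid, approach=SurgicalApproach((0, 0, 1)))

    def test_no_flanges_identity(self):
        des = self._design()
        out = add_flanges(des, [], CrossSectionPlane((0, 0, 0), (1, 0, 0)))
        assert out is des

    def test_tabs_add_volume_and_region(self):
        des = self._design()
        tab1 = lv.box([10, 2, 0], [14, 4, 4], H, bounds=([0, 0, 0], [16, 10, 4]))
        tab2 = lv.box([10, 6, 0], [14, 8, 4], H, bounds=([0, 0, 0], [16, 10, 4]))
        # demarcation just off the body face so the body's boundary layer
        # does not count as flange; normal points toward the tabs
        plane = CrossSectionPlane((10.1, 0, 0), (1, 0, 0))
        out = add_flanges(des, [tab1, tab2], plane)
        expect = des.solid.volume() + tab1.volume() + tab2.volume()
        assert out.solid.volume() == pytest.approx(expect, rel=0.02)
        assert out.flange_region is not None
        assert out.flange_region.volume() == pytest.approx(
            tab1.volume() + tab2.volume(), rel=0.05)

    def test_floating_flange_warns(self):
        des = self._design()
        far = lv.box([50, 0, 0], [54, 2, 4], H)
        with pytest.warns(UserWarning, match="floating"):
            add_flanges(des, [far], CrossSectionPlane((40.0, 0, 0), (1, 0, 0)))

    def test_demarcation_beyond_flanges_warns_empty_region(self):
        des = self._design()
        tab = lv.box([10, 2, 0], [14, 4, 4], H, bounds=([0, 0, 0], [16, 10, 4]))
        with pytest.warns(UserWarning, match="empty flange region"):
            out = add_flanges(des, [tab], CrossSectionPlane((99.0, 0, 0), (1, 0, 0)))
        assert out.flange_region.is_empty()
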