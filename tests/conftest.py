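import numpy as np
import pytest
import trimesh

from bonescaffold import levelset as lv


@pytest.fixture(scope="session")
def sphere_mesh():
    return trimesh.creation.icosphere(subdivisions=4, radius=5.0)


@pytest.fixture(scope="session")
def cube_mesh():
    return trimesh.creation.box(extents=[1.0, 1.0, 1.0])


@pytest.fixture(scope="session")
def sphere_ls():
    return lv.sphere([0.0, 0.0, 0.0], 5.0, 0.25)


@pytest.fixture(scope="session")
def two_cylinder_defect():
    """Segmental-defect analogue: two coaxial solid cylinders with a gap."""
    c1 = trimesh.creation.cylinder(
        radius=5.0, height=10.0, sections=64,
        transform=trimesh.transformations.translation_matrix([0, 0, -10.0]))
    c2 = trimesh.creation.cylinder(
        radius=5.0, height=10.0, sections=64,
        transform=trimesh.transformations.translation_matrix([0, 0, 10.0]))
    return trimesh.util.concatenate([c1, c2])


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """End-to-end design runs for the three synthetic defect cases, shared
    by the printability-matrix and insertability checks."""
    from bonescaffold.case import CaseDescription
    from bonescaffold.fixtures import FixtureSpec, make_defect_mesh
    from bonescaffold.mesh_io import write_mesh
    from bonescaffold.pipeline import run_case

    base = tmp_path_factory.mktemp("pipelines")
    runs = {}
    cases = {
        "segmental_tube": dict(
            spec=FixtureSpec(kind="segmental_tube"),
            case=dict(
                voxel_size=0.8,
                fill=dict(method="segmental",
                          plane_a=dict(point=(0, 0, 38.0), normal=(0, 0, 1)),
                          plane_b=dict(point=(0, 0, 82.0), normal=(0, 0, 1))),
                approach=dict(direction=(-1, 0, 0)),
                architecture=dict(family="lattice", variant="bcc",
                                  cell_size=5.0, thickness=1.2,
                                  shell_thickness=0.8))),
        "notched_tube": dict(
            spec=FixtureSpec(kind="notched_tube", mesh_h=0.4),
            case=dict(
                voxel_size=0.25,
                fill=dict(method="minor_closing", distance=1.0),
                approach=dict(direction=(-1, 0, 0)),
                architecture="solid")),
        "cranial_plate": dict(
            spec=FixtureSpec(kind="cranial_plate", mesh_h=0.5),
            case=dict(
                voxel_size=0.5,
                fill=dict(method="guided",
                          opening_plane=dict(point=(0, 0, 60.0),
                                             normal=(0, 0, 1)),
                          depth=4.5),
                approach=dict(direction=(0, 0, -1)),
                architecture=dict(family="tpms", variant="gyroid",
                                  cell_size=5.0, thickness=1.0))),
    }
    import warnings

    for name, cfg in cases.items():
        d = base / name
        d.mkdir()
        mesh = make_defect_mesh(cfg["spec"])
        write_mesh(mesh, d / "defect.stl")
        body = dict(name=name, rng_seed=11, defect_mesh="defect.stl",
                    clearance=0.1, output_dir="out", **cfg["case"])
        case = CaseDescription.model_validate(body)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            runs[name] = run_case(case, base_dir=d)
    return runs


def indicator_on(ls, grid):
    """Interior indicator re-embedded on a reference grid."""
    return lv.to_grid(ls, grid).indicator()


def common_grid(a, b):
    return lv._common_grid(a, b)
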