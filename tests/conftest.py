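"""Shared fixtures: verification blocks, coarse phantoms and the
session-level fracture runs reused by the property and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

import vertfrac as vf
from vertfrac.calibration import MaterialField
from vertfrac.regions import TRABECULAR


@pytest.fixture(scope="session")
def block10():
    """Homogeneous 10 mm trabecular block, 1 mm voxels."""
    return vf.build_block_phantom((10.0, 10.0, 10.0), 300.0, 1.0)


@pytest.fixture(scope="session")
def coarse_spec():
    """Down-scaled vertebral phantom (3 mm voxels, no screws) used for the
    fracture-property runs."""
    return vf.PhantomSpec(
        semi_axis_x_mm=15.0,
        semi_axis_y_mm=12.0,
        height_mm=21.0,
        voxel_spacing_mm=(3.0, 3.0, 3.0),
        screw_spec=None,
        hu_noise_sd=25.0,
        rng_seed=1,
    )


@pytest.fixture(scope="session")
def coarse_volume(coarse_spec):
    return vf.build_vertebra_phantom(coarse_spec)


@pytest.fixture(scope="session")
def screw_volume():
    """Default-geometry phantom with screws at 3 mm voxels."""
    return vf.build_vertebra_phantom(
        vf.PhantomSpec(voxel_spacing_mm=(3.0, 3.0, 3.0), rng_seed=2)
    )


def uniaxial_bcs(model):
    """Replace the fully-fixed bottom by z-only support plus minimal
    rigid-body constraints, giving an exact uniform uniaxial state."""
    bot = model.node_sets["bottom"]
    nodes = model.nodes[bot]
    corner = bot[np.lexsort((nodes[:, 1], nodes[:, 0]))[0]]
    edge = bot[np.lexsort((-nodes[:, 1], nodes[:, 0]))[0]]
    model.dirichlet_dofs = np.concatenate(
        [3 * bot + 2, [3 * corner, 3 * corner + 1, 3 * edge]]
    )
    model._cache.clear()
    return model


def single_element_model(E=1000.0, nu=0.3, rho_ash=0.5, tension=True):
    """One 1 mm voxel under exact uniaxial tension/compression."""
    vol = vf.build_block_phantom((1.0, 1.0, 1.0), 300.0, 1.0)
    field = MaterialField(
        E=np.array([E]),
        nu=np.array([nu]),
        rho_app=np.array([1.0]),
        rho_ash=np.array([rho_ash]),
        region=np.array([TRABECULAR], dtype=np.int8),
    )
    direction = (0.0, 0.0, 1.0) if tension else (0.0, 0.0, -1.0)
    lc = vf.LoadCase(
        direction=direction,
        moment_nmm=0.0,
        body_fraction=1.0,
        facet_fraction_of_body=0.0,
    )
    model = vf.mesh_from_volume(vol, field, load_case=lc)
    return uniaxial_bcs(model)


@pytest.fixture(scope="session")
def coarse_runs(coarse_volume, coarse_spec):
    """Fracture runs on the coarse phantom under the bending analogue with
    the strain criterion: lesion-free, single osteolytic lesions and the
    three-lesion combination."""
    positions = vf.default_lesion_positions(coarse_spec)
    field0 = vf.build_material_field(coarse_volume)
    model = vf.mesh_from_volume(
        coarse_volume, field0, load_case=vf.lateral_bending_load()
    )
    schedule = vf.LoadSchedule(delta_f=2000.0, max_steps=60)
    criterion = vf.FailureCriterion(kind="strain")

    def run(lesions):
        field = vf.build_material_field(coarse_volume, None, lesions)
        return vf.run_fracture(model, field, criterion, schedule)

    results = {"none": run([])}
    results["P1_R5"] = run([vf.Lesion(center=positions["P1"], radius=5.0)])
    for p in ("P1", "P2", "P3"):
        results[f"{p}_R10"] = run([vf.Lesion(center=positions[p], radius=10.0)])
    results["multi_R10"] = run(
        [vf.Lesion(center=positions[p], radius=10.0) for p in ("P1", "P2", "P3")]
    )
    return results


@pytest.fixture(scope="session")
def moment_free_run(coarse_volume):
    """Proportional (moment-free) compressive ramp on the coarse phantom:
    under pure force scaling the secant compliance u/f is the tangent
    compliance of the current damaged structure, hence monotone."""
    field = vf.build_material_field(coarse_volume)
    lc = vf.LoadCase(
        direction=(0.0, 0.0, -1.0),
        moment_nmm=0.0,
        body_fraction=1.0,
        facet_fraction_of_body=0.3,
    )
    model = vf.mesh_from_volume(coarse_volume, field, load_case=lc)
    schedule = vf.LoadSchedule(delta_f=4000.0, max_steps=60)
    return vf.run_fracture(
        model, field, vf.FailureCriterion(kind="strain"), schedule
    )


@pytest.fixture(scope="session")
def full_phantom_run():
    """One fracture run on the full-resolution instrumented phantom
    (2 mm voxels, ~5k elements), bending analogue, strain criterion."""
    import time

    spec = vf.PhantomSpec(rng_seed=1)
    volume = vf.build_vertebra_phantom(spec)
    field = vf.build_material_field(volume)
    model = vf.mesh_from_volume(
        volume, field, load_case=vf.lateral_bending_load()
    )
    schedule = vf.LoadSchedule(delta_f=1000.0, max_steps=80)
    t0 = time.time()
    result = vf.run_fracture(
        model, field, vf.FailureCriterion(kind="strain"), schedule
    )
    return result, time.time() - t0, model
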