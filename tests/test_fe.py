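"""FE core verification: patch test, equilibrium, beam oracle, dense solve."""

import numpy as np
import pytest

import vertfrac as vf
from vertfrac.calibration import MaterialField
from vertfrac.regions import SCREW

from conftest import uniaxial_bcs


def _uniform_load_case(direction=(0.0, 0.0, -1.0)):
    return vf.LoadCase(
        direction=direction,
        moment_nmm=0.0,
        body_fraction=1.0,
        facet_fraction_of_body=0.0,
    )


class TestMeshing:
    def test_structured_block_counts(self, block10):
        field = vf.calibrate(block10)
        model = vf.mesh_from_volume(block10, field)
        assert len(model.conn) == 1000
        assert len(model.nodes) == 11**3

    def test_element_count_equals_in_body_voxels(self, coarse_volume):
        field = vf.calibrate(coarse_volume)
        model = vf.mesh_from_volume(coarse_volume, field)
        assert len(model.conn) == int(coarse_volume.in_body_mask().sum())

    def test_screw_elements_carry_screw_material(self, screw_volume):
        field = vf.calibrate(screw_volume)
        model = vf.mesh_from_volume(screw_volume, field)
        screws = model.material.region == SCREW
        assert screws.sum() > 0
        assert np.all(model.material.E[screws] == 110_000.0)
        assert np.all(model.material.nu[screws] == 0.4)
        assert len(model.node_sets["screw_head"]) > 0

    def test_empty_body_is_an_error(self):
        from vertfrac.volume import HUVolume
        from vertfrac.regions import OUTSIDE

        vol = HUVolume(
            np.zeros((3, 3, 3)),
            np.full((3, 3, 3), OUTSIDE, dtype=np.int8),
            (1.0, 1.0, 1.0),
            (0.0, 0.0, 0.0),
        )
        empty = MaterialField(*(np.empty(0) for _ in range(4)), np.empty(0, np.int8))
        with pytest.raises(ValueError, match="no in-body"):
            vf.mesh_from_volume(vol, empty)


class TestPatchAndEquilibrium:
    def test_uniform_compression_patch_test(self, block10):
        field = vf.calibrate(block10)
        model = uniaxial_bcs(
            vf.mesh_from_volume(block10, field, load_case=_uniform_load_case())
        )
        sol = vf.solve_elastic(model, 1000.0)
        # sigma_zz = -F/A = -10 MPa exactly, other components zero
        assert np.allclose(sol.stress[:, 2], -10.0, atol=1e-8)
        assert np.allclose(sol.stress[:, [0, 1, 3, 4, 5]], 0.0, atol=1e-8)

    def test_reaction_equals_applied_load(self, block10):
        field = vf.calibrate(block10)
        model = vf.mesh_from_volume(block10, field, load_case=_uniform_load_case())
        sol = vf.solve_elastic(model, 1234.0)
        f_r, _ = vf.reaction_and_displacement(model, sol)
        assert f_r == pytest.approx(1234.0, rel=1e-6)
        # global equilibrium: upward bottom reactions balance the -z load
        bottom = model.node_sets["bottom"]
        assert np.sum(sol.internal_force[bottom, 2]) == pytest.approx(
            1234.0, rel=1e-6
        )

    def test_displacement_is_linear_in_load(self, block10):
        field = vf.calibrate(block10)
        model = vf.mesh_from_volume(block10, field, load_case=_uniform_load_case())
        _, u1 = vf.reaction_and_displacement(model, vf.solve_elastic(model, 500.0))
        _, u2 = vf.reaction_and_displacement(model, vf.solve_elastic(model, 1000.0))
        assert u2 == pytest.approx(2 * u1, rel=1e-9)

    def test_zero_load_gives_zero_displacement(self, block10):
        field = vf.calibrate(block10)
        model = vf.mesh_from_volume(block10, field, load_case=_uniform_load_case())
        _, u = vf.reaction_and_displacement(model, vf.solve_elastic(model, 0.0))
        assert u == 0.0

    def test_missing_top_set_is_an_error(self, block10):
        field = vf.calibrate(block10)
        model = vf.mesh_from_volume(block10, field, load_case=_uniform_load_case())
        sol = vf.solve_elastic(model, 100.0)
        model.node_sets["top"] = np.array([], dtype=int)
        with pytest.raises(ValueError, match="end-plate"):
            vf.reaction_and_displacement(model, sol)


def test_cantilever_tip_deflection_matches_beam_theory():
    """Slender cantilever under a tip load: Euler-Bernoulli PL^3/3EI."""
    vol = vf.build_block_phantom((2.0, 2.0, 20.0), 300.0, 0.5)
    field = vf.calibrate(vol)
    model = vf.mesh_from_volume(vol, field)
    P = 1.0
    f = np.zeros(model.n_dofs)
    top = model.node_sets["top"]
    w = model.set_weights["top"]
    f.reshape(-1, 3)[top, 0] = P * w / w.sum()
    sol = vf.solve_elastic(model, external_force=f)
    tip = float(np.mean(sol.displacement[top, 0]))
    E = field.E[0]
    L, I = 20.0, 2.0 * 2.0**3 / 12.0
    assert tip == pytest.approx(P * L**3 / (3 * E * I), rel=0.10)


def test_sparse_matches_dense_solve_below_300_dofs():
    vol = vf.build_block_phantom((3.0, 3.0, 3.0), 500.0, 1.0)
    field = vf.calibrate(vol)
    model = vf.mesh_from_volume(vol, field, load_case=_uniform_load_case())
    model._ensure_cache()
    K = model.assemble()
    free = model._cache["free"]
    assert free.sum() <= 300
    f = model.load_case.nodal_forces(model, 100.0)
    u_sparse = vf.solve_elastic(model, 100.0).displacement.ravel()[free]
    u_dense = np.linalg.solve(K[free][:, free].toarray(), f[free])
    assert np.allclose(u_sparse, u_dense, atol=1e-10 * np.abs(u_dense).max())


def test_stiffness_is_symmetric_positive_definite():
    vol = vf.build_block_phantom((3.0, 3.0, 3.0), 500.0, 1.0)
    field = vf.calibrate(vol)
    model = vf.mesh_from_volume(vol, field)
    model._ensure_cache()
    K = model.assemble()
    assert abs(K - K.T).max() < 1e-8 * abs(K).max()
    free = model._cache["free"]
    eigs = np.linalg.eigvalsh(K[free][:, free].toarray())
    assert eigs.min() > 0


def test_frame_objectivity_under_quarter_turn():
    """A lateral tip load in x on a square-section cantilever maps onto the
    y-load solution under the 90-degree rotation (x,y) -> (y,-x)."""
    vol = vf.build_block_phantom((4.0, 4.0, 8.0), 500.0, 1.0)
    field = vf.calibrate(vol)
    model = vf.mesh_from_volume(vol, field)
    top = model.node_sets["top"]
    w = model.set_weights["top"]

    def tip_solution(axis):
        f = np.zeros(model.n_dofs)
        f.reshape(-1, 3)[top, axis] = 10.0 * w / w.sum()
        return vf.solve_elastic(model, external_force=f)

    sol_x, sol_y = tip_solution(0), tip_solution(1)
    # u_y(p) = S u_x(S^-1 p) for the +90-degree turn S(v) = (-v_y, v_x, v_z)
    preimage = np.column_stack(
        [model.nodes[:, 1], -model.nodes[:, 0], model.nodes[:, 2]]
    )
    idx = {tuple(np.round(p, 9)): i for i, p in enumerate(model.nodes)}
    perm = np.array([idx[tuple(np.round(p, 9))] for p in preimage])
    ux_mapped = sol_x.displacement[perm]
    expected = np.column_stack(
        [-ux_mapped[:, 1], ux_mapped[:, 0], ux_mapped[:, 2]]
    )
    assert np.allclose(sol_y.displacement, expected, atol=1e-10)


def test_moment_load_is_statically_equivalent():
    """The end-plate moment distribution has zero net force and the
    requested resultant moment about the end-plate centroid."""
    vol = vf.build_block_phantom((10.0, 10.0, 10.0), 300.0, 1.0)
    field = vf.calibrate(vol)
    lc = vf.LoadCase(
        moment_nmm=4700.0,
        moment_axis=(1.0, 0.0, 0.0),
        body_fraction=1.0,
        facet_fraction_of_body=0.0,
    )
    model = vf.mesh_from_volume(vol, field, load_case=lc)
    f = lc.nodal_forces(model, 0.0).reshape(-1, 3)
    assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)
    top = model.node_sets["top"]
    w = model.set_weights["top"]
    centroid = (w[:, None] * model.nodes[top]).sum(axis=0) / w.sum()
    moments = np.cross(model.nodes[top] - centroid, f[top]).sum(axis=0)
    assert moments[0] == pytest.approx(4700.0, rel=1e-9)
    assert abs(moments[1]) < 1e-9 and abs(moments[2]) < 1e-9


def test_phantom_load_split_between_body_and_screws(screw_volume):
    field = vf.calibrate(screw_volume)
    model = vf.mesh_from_volume(
        screw_volume, field, load_case=vf.lateral_bending_load()
    )
    sol = vf.solve_elastic(model, 1000.0)
    f_r, _ = vf.reaction_and_displacement(model, sol)
    # 80% of the load goes through the superior end plate + facet analogue
    assert f_r == pytest.approx(800.0, rel=1e-6)
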