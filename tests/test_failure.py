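"""Failure criteria: local measures, density-dependent limits, element kill."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vertfrac as vf
from vertfrac.calibration import E_KILLED_MPA, MaterialField
from vertfrac.regions import CORTICAL, FAILED, SCREW, TRABECULAR

from conftest import single_element_model


def _fake_solution(principal_strains=None, principal_stresses=None, n=1):
    """Minimal stand-in solution carrying only the recovered principals."""

    class _S:
        pass

    s = _S()
    s.principal_strains = (
        np.zeros((n, 3)) if principal_strains is None else np.atleast_2d(principal_strains)
    )
    s.principal_stresses = (
        np.zeros((n, 3)) if principal_stresses is None else np.atleast_2d(principal_stresses)
    )
    return s


def _field(n=1, region=TRABECULAR, rho_ash=0.5):
    return MaterialField(
        E=np.full(n, 1000.0),
        nu=np.full(n, 0.3),
        rho_app=np.full(n, 1.0),
        rho_ash=np.full(n, rho_ash),
        region=np.full(n, region, dtype=np.int8),
    )


class TestLocalMeasures:
    @pytest.mark.parametrize(
        "principals,expected",
        [
            ((10.0, 2.0, -5.0), (10.0, 5.0)),
            ((0.0, 0.0, 0.0), (0.0, 0.0)),
            ((-1.0, -2.0, -3.0), (0.0, 3.0)),
        ],
        ids=["mixed", "null", "all-compressive"],
    )
    def test_examples(self, principals, expected):
        assert vf.local_stress_measures(principals) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.tuples(*[st.floats(-100, 100) for _ in range(3)]))
    def test_matches_brute_force(self, principals):
        plus, minus = vf.local_stress_measures(principals)
        assert plus == max(0.0, *principals)
        assert minus == -min(0.0, *principals)
        assert plus >= 0 and minus >= 0


class TestStressLimits:
    def test_unit_density_trabecular(self):
        plus, minus = vf.stress_limits(1.0, "trabecular")
        assert minus == pytest.approx(137.0)
        assert plus == pytest.approx(109.6)

    def test_unit_density_cortical(self):
        _, minus = vf.stress_limits(1.0, "cortical")
        assert minus == pytest.approx(114.0)

    def test_power_law_at_ash_density_of_unit_apparent(self):
        rho_ash = vf.density_to_ash(1.0)
        _, minus = vf.stress_limits(rho_ash, "trabecular")
        assert minus == pytest.approx(137.0 * rho_ash**1.88)
        assert minus == pytest.approx(43.9, abs=0.1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.floats(0.01, 1.2),
        st.floats(0.01, 1.2),
        st.sampled_from(["trabecular", "cortical"]),
    )
    def test_limits_increase_with_ash_density(self, a, b, region):
        lo, hi = sorted((a, b))
        assert vf.stress_limits(lo, region)[1] <= vf.stress_limits(hi, region)[1]


class TestEvaluateFailure:
    strain_crit = vf.FailureCriterion(kind="strain")
    stress_crit = vf.FailureCriterion(kind="stress")

    def test_tensile_strain_above_limit_fails(self):
        sol = _fake_solution(principal_strains=(0.8e-2, 0.0, 0.0))
        assert list(vf.evaluate_failure(sol, _field(), self.strain_crit)) == [0]

    def test_compressive_strain_below_limit_survives(self):
        sol = _fake_solution(principal_strains=(0.0, 0.0, -1.0e-2))
        assert len(vf.evaluate_failure(sol, _field(), self.strain_crit)) == 0

    def test_strict_inequality_at_the_limit(self):
        sol = _fake_solution(principal_strains=(0.73e-2, 0.0, 0.0))
        assert len(vf.evaluate_failure(sol, _field(), self.strain_crit)) == 0

    def test_zero_state_never_fails(self):
        sol = _fake_solution()
        for crit in (self.strain_crit, self.stress_crit):
            assert len(vf.evaluate_failure(sol, _field(), crit)) == 0

    def test_screw_and_failed_elements_are_never_tested(self):
        sol = _fake_solution(
            principal_strains=[(0.1, 0, 0), (0.1, 0, 0), (0.1, 0, 0)], n=3
        )
        field = _field(n=3)
        field.region[1] = SCREW
        field.region[2] = FAILED
        assert list(vf.evaluate_failure(sol, field, self.strain_crit)) == [0]

    def test_stress_criterion_uses_region_specific_limits(self):
        # 40 MPa tension at ash density 0.6: above the cortical tensile
        # limit (~37.9 MPa) but below the trabecular one (~42.0 MPa)
        rho_ash = 0.6
        sol = _fake_solution(principal_stresses=[(40.0, 0, 0), (40.0, 0, 0)], n=2)
        field = _field(n=2, rho_ash=rho_ash)
        field.region[1] = CORTICAL
        lim_t = 0.8 * 137.0 * rho_ash**1.88
        lim_c = 0.8 * 114.0 * rho_ash**1.72
        assert lim_c < 40.0 < lim_t
        assert list(vf.evaluate_failure(sol, field, self.stress_crit)) == [1]

    def test_unknown_criterion_kind_is_an_error(self):
        with pytest.raises(ValueError):
            vf.FailureCriterion(kind="energy")

    def test_failed_set_matches_per_element_recheck(self, coarse_volume):
        field = vf.build_material_field(coarse_volume)
        model = vf.mesh_from_volume(
            coarse_volume, field, load_case=vf.lateral_bending_load()
        )
        sol = vf.solve_elastic(model, 16_000.0)
        got = set(vf.evaluate_failure(sol, field, self.strain_crit))
        expected = set()
        for e in range(field.n_elements):
            if field.region[e] not in (TRABECULAR, CORTICAL):
                continue
            eps = sol.principal_strains[e]
            plus, minus = max(0.0, *eps), -min(0.0, *eps)
            if plus > 0.73e-2 or minus > 1.04e-2:
                expected.add(e)
        assert got == expected
        assert len(expected) > 0


class TestKill:
    def test_kill_nothing_is_identity(self):
        field = _field(n=3)
        out = vf.kill_elements(field, [])
        assert np.array_equal(out.E, field.E)

    def test_kill_one_element_exactly(self):
        field = _field(n=3)
        out = vf.kill_elements(field, [1])
        assert out.E[1] == E_KILLED_MPA
        assert out.region[1] == FAILED
        assert np.array_equal(out.E[[0, 2]], field.E[[0, 2]])
        assert np.array_equal(out.nu, field.nu)  # nu untouched

    def test_kill_is_idempotent(self):
        field = _field(n=3)
        once = vf.kill_elements(field, [1])
        twice = vf.kill_elements(once, [1])
        assert np.array_equal(once.E, twice.E)
        assert np.array_equal(once.region, twice.region)

    def test_killing_a_screw_element_is_an_error(self):
        field = _field(n=2)
        field.region[0] = SCREW
        with pytest.raises(ValueError, match="screw"):
            vf.kill_elements(field, [0])


class TestCriterionScaleInvariance:
    """Uniaxial single-element ramps: the strain criterion triggers at a
    fixed strain regardless of stiffness; the stress criterion at the
    ash-density limit regardless of strain."""

    @pytest.mark.parametrize("E", [1000.0, 5000.0])
    def test_strain_threshold_is_density_and_stiffness_independent(self, E):
        model = single_element_model(E=E, tension=True)
        crit = vf.FailureCriterion(kind="strain")
        # area is 1 mm^2, so the axial stress equals the applied force
        threshold = 0.73e-2 * E
        for f in (0.999 * threshold, 1.001 * threshold):
            sol = vf.solve_elastic(model, f)
            failed = vf.evaluate_failure(sol, model.material, crit)
            assert (len(failed) == 1) == (f > threshold)

    def test_stress_threshold_follows_ash_density(self):
        rho_ash = 0.7
        model = single_element_model(E=2000.0, rho_ash=rho_ash, tension=True)
        crit = vf.FailureCriterion(kind="stress")
        threshold = 0.8 * 137.0 * rho_ash**1.88
        for f in (0.999 * threshold, 1.001 * threshold):
            sol = vf.solve_elastic(model, f)
            failed = vf.evaluate_failure(sol, model.material, crit)
            assert (len(failed) == 1) == (f > threshold)
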