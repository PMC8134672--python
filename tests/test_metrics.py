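"""Summary statistics: implant peaks, region averages, bite force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mandifem.mesh import box_mesh
from mandifem.fem import FieldResult
from mandifem.metrics import (peak_von_mises, region_average_principal_strains,
                              bite_force, RegionSummary, ImplantPeak,
                              mesh_convergence_study)


def fake_result(vm=None, principal=None, n=None, reactions=None):
    if n is None:
        n = len(vm) if vm is not None else len(principal)
    return FieldResult(
        displacements=np.zeros((1, 3)),
        element_strain=np.zeros((n, 3, 3)),
        element_stress=np.zeros((n, 3, 3)),
        principal_strains=(principal if principal is not None
                           else np.zeros((n, 3))),
        von_mises=vm if vm is not None else np.zeros(n),
        reactions=reactions or {})


def brute_force_peak(values, exclude_frac=0.001, n_avg=10):
    """Plain-python reference: sort, drop ceil(0.1%), average next ten."""
    import math
    ordered = sorted(values, reverse=True)
    drop = math.ceil(exclude_frac * len(ordered))
    return sum(ordered[drop:drop + n_avg]) / n_avg


class TestPeakVonMises:
    def test_thousand_elements_drops_one_value(self):
        vm = np.arange(1.0, 1001.0)
        mesh = _mesh_with_set(1000)
        peak = peak_von_mises(fake_result(vm=vm), mesh, "implant")
        # drop {1000}, average {999..990}
        assert peak.peak_von_mises == pytest.approx(994.5)
        assert peak.exceeded_yield is True

    def test_two_thousand_elements_drops_two_values(self):
        vm = np.arange(1.0, 2001.0)
        mesh = _mesh_with_set(2000)
        peak = peak_von_mises(fake_result(vm=vm), mesh, "implant")
        assert peak.peak_von_mises == pytest.approx(1993.5)

    def test_constant_field_returns_the_constant(self):
        for n in (12, 100, 5000):
            vm = np.full(n, 7.25)
            peak = peak_von_mises(fake_result(vm=vm), _mesh_with_set(n),
                                  "implant")
            assert peak.peak_von_mises == pytest.approx(7.25)
            assert peak.exceeded_yield is False

    def test_too_few_elements_rejected(self):
        with pytest.raises(ValueError, match="elements"):
            peak_von_mises(fake_result(vm=np.ones(10)), _mesh_with_set(10),
                           "implant")

    def test_matches_brute_force_oracle_on_many_random_fields(self):
        """1000 random fields against the plain-python sort oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(12, 3000))
            vm = rng.gamma(2.0, 100.0, size=n)
            got = peak_von_mises(fake_result(vm=vm), _mesh_with_set(n),
                                 "implant").peak_von_mises
            assert got == pytest.approx(brute_force_peak(vm), rel=1e-12)

    @given(st.integers(12, 4000), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_property_matches_oracle(self, n, seed):
        vm = np.random.default_rng(seed).exponential(200.0, size=n)
        got = peak_von_mises(fake_result(vm=vm), _mesh_with_set(n),
                             "implant").peak_von_mises
        assert got == pytest.approx(brute_force_peak(vm), rel=1e-12)

    def test_yield_flag_threshold_fidelity(self):
        vm = np.full(50, 880.0)
        peak = peak_von_mises(fake_result(vm=vm), _mesh_with_set(50),
                              "implant")
        assert peak.exceeded_yield is False  # equality is not exceedance


def _mesh_with_set(n):
    """Box mesh truncated/tagged so that "implant" has exactly n elements."""
    import math
    k = max(1, math.ceil((n / 6) ** (1 / 3)))
    m = box_mesh((1, 1, 1), (k, k, max(1, math.ceil(n / (6 * k * k)))))
    while m.n_elements < n:
        k += 1
        m = box_mesh((1, 1, 1), (k, k, k))
    m.element_sets["implant"] = np.arange(n)
    return m


class TestRegionAverages:
    def test_constant_field_region_independent(self):
        m = box_mesh((1, 1, 1), (2, 2, 2))
        pr = np.tile([3e-4, 1e-4, -2e-4], (m.n_elements, 1))
        res = fake_result(principal=pr, n=m.n_elements)
        m.element_sets["some"] = np.arange(5)
        s = region_average_principal_strains(res, m, "some")
        assert s.avg_max_principal == pytest.approx(300.0)
        assert s.avg_min_principal == pytest.approx(-200.0)

    def test_equal_volume_elements_arithmetic_mean(self):
        m = box_mesh((1, 1, 1), (1, 1, 1))  # 6 equal-volume tets
        pr = np.zeros((6, 3))
        pr[:, 0] = [100e-6, 300e-6, 100e-6, 300e-6, 100e-6, 300e-6]
        res = fake_result(principal=pr, n=6)
        s = region_average_principal_strains(res, m, np.arange(6))
        assert s.avg_max_principal == pytest.approx(200.0)

    def test_matches_naive_summation_oracle(self, human_coarse):
        rng = np.random.default_rng(7)
        n = human_coarse.n_elements
        pr = np.sort(rng.normal(0, 1e-3, size=(n, 3)), axis=1)[:, ::-1]
        res = fake_result(principal=pr, n=n)
        region = rng.choice(n, size=500, replace=False)
        s = region_average_principal_strains(res, human_coarse, region)
        vols = human_coarse.volumes()
        num1 = sum(vols[e] * pr[e, 0] for e in region)
        num3 = sum(vols[e] * pr[e, 2] for e in region)
        den = sum(vols[e] for e in region)
        assert s.avg_max_principal == pytest.approx(num1 / den * 1e6, rel=1e-9)
        assert s.avg_min_principal == pytest.approx(num3 / den * 1e6, rel=1e-9)

    def test_invariant_to_element_enumeration_order(self, human_coarse):
        rng = np.random.default_rng(11)
        n = human_coarse.n_elements
        pr = np.sort(rng.normal(0, 1e-3, size=(n, 3)), axis=1)[:, ::-1]
        res = fake_result(principal=pr, n=n)
        region = rng.choice(n, size=200, replace=False)
        a = region_average_principal_strains(res, human_coarse, region)
        b = region_average_principal_strains(res, human_coarse,
                                             region[::-1])
        assert a.avg_max_principal == pytest.approx(b.avg_max_principal,
                                                    rel=1e-12)

    def test_empty_region_rejected(self, human_coarse):
        from mandifem.mesh import MeshError
        with pytest.raises(MeshError):
            region_average_principal_strains(fake_result(n=1), human_coarse,
                                             [])

    def test_summary_invariant_enforced(self):
        with pytest.raises(ValueError):
            RegionSummary(region="r", avg_max_principal=-10.0,
                          avg_min_principal=10.0)


class TestImplantPeakInvariants:
    def test_negative_peak_rejected(self):
        with pytest.raises(ValueError):
            ImplantPeak(implant="p", peak_von_mises=-1.0, exceeded_yield=False)

    def test_inconsistent_yield_flag_rejected(self):
        with pytest.raises(ValueError):
            ImplantPeak(implant="p", peak_von_mises=900.0,
                        exceeded_yield=False)


class TestBiteForce:
    def _solved(self, scale=1.0):
        from mandifem.materials import material_registry
        from mandifem.muscles import (clenching_task, build_load_case,
                                      muscle_groups)
        from mandifem.fem import assemble_stiffness, solve_static
        import dataclasses
        mesh = self._mesh
        task = clenching_task("ICP", "human")
        if scale != 1.0:
            task = dataclasses.replace(task, activations={
                k: scale * v for k, v in task.activations.items()})
        case = build_load_case(mesh, muscle_groups("human"), task)
        res = solve_static(assemble_stiffness(
            mesh, material_registry("human")), case)
        return task, case, res

    @pytest.fixture(autouse=True)
    def _setup(self, human_coarse):
        self._mesh = human_coarse

    def test_closing_bite_force_positive_and_bounded_by_applied_load(self):
        """Equilibrium bound: the occlusal reaction cannot exceed the total
        applied vertical muscle force."""
        task, case, res = self._solved()
        bf = bite_force(res, self._mesh, task.occlusal_sets)
        total_up = case.total_force()[2]
        assert 0.0 < bf < total_up

    def test_bite_force_linear_in_activation(self):
        task1, _, res1 = self._solved(1.0)
        task2, _, res2 = self._solved(0.5)
        bf1 = bite_force(res1, self._mesh, task1.occlusal_sets)
        bf2 = bite_force(res2, self._mesh, task2.occlusal_sets)
        assert bf2 == pytest.approx(0.5 * bf1, rel=1e-9)

    def test_zero_activation_zero_bite(self):
        _, _, res = self._solved(0.0)
        task, _, _ = self._solved(0.0)
        assert bite_force(res, self._mesh, task.occlusal_sets) == \
            pytest.approx(0.0, abs=1e-9)

    def test_unconstrained_occlusion_rejected(self):
        task, case, res = self._solved()
        with pytest.raises(ValueError):
            bite_force(res, self._mesh, ["SM_L"])


class TestConvergenceProtocol:
    def test_ladder_must_be_decreasing_and_deep_enough(self):
        from mandifem.anatomy import HUMAN_DEFAULTS
        with pytest.raises(ValueError, match="decreasing"):
            mesh_convergence_study(HUMAN_DEFAULTS, [4.0, 5.0, 6.0])
        with pytest.raises(ValueError, match="levels"):
            mesh_convergence_study(HUMAN_DEFAULTS, [6.0, 5.0])

    def test_three_level_ladder_self_error_zero_and_errors_decrease(self):
        """Finest level has zero error against itself; linear 4-node tets
        on a coarse ladder show decreasing error with refinement."""
        from mandifem.anatomy import HUMAN_DEFAULTS
        df = mesh_convergence_study(HUMAN_DEFAULTS, [10.0, 8.0, 6.0],
                                    quadratic=False)
        assert df.iloc[-1].max_err_pct == 0.0
        errs = df.err_avg_von_mises_pct.to_numpy()
        assert errs[-2] <= errs[0] + 1e-9  # allow one small inversion
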