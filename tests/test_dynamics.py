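"""Constitutive curves, pennation geometry and fiber-length solvers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myogait import (
    CurveSet,
    MuscleTendonUnit,
    PathPoint,
    default_curves,
    pennation_angle,
    rigid_tendon_fiber_length,
    simulate_fiber_trajectory,
    static_equilibrium_fiber_length,
)

from conftest import compliant_unit, rigid_unit


class TestCurves:
    def test_anchor_values(self, curves):
        assert float(curves.active_fl(1.0)) == 1.0
        assert float(curves.passive_fl(1.0)) == 0.0
        assert float(curves.passive_fl(0.7)) == 0.0
        assert float(curves.passive_fl(1.7)) == pytest.approx(1.0, abs=1e-12)
        assert float(curves.force_velocity(0.0)) == 1.0
        assert float(curves.force_velocity(-1.0)) == 0.0
        assert float(curves.tendon(0.0)) == 0.0
        assert float(curves.tendon(curves.eps_o)) == 1.0

    def test_force_velocity_monotone_with_eccentric_plateau(self, curves):
        v = np.linspace(-1.0, 20.0, 400)
        f = curves.force_velocity(v)
        assert np.all(np.diff(f) > 0)
        assert f.max() < 1.4

    def test_passive_curve_nondecreasing(self, curves):
        l = np.linspace(0.5, 2.0, 300)
        assert np.all(np.diff(curves.passive_fl(l)) >= 0)

    def test_tendon_strictly_increasing_for_positive_strain(self, curves):
        e = np.linspace(1e-6, 0.15, 300)
        assert np.all(np.diff(curves.tendon(e)) > 0)

    @pytest.mark.parametrize("eps_o", [0.02, 0.049, 0.09])
    def test_tendon_inverse_roundtrip(self, eps_o):
        c = CurveSet(eps_o=eps_o)
        assert float(c.tendon(eps_o)) == 1.0
        f = np.linspace(1e-6, 2.5, 200)
        np.testing.assert_allclose(c.tendon(c.tendon_inverse(f)), f, atol=1e-10)
        e = np.linspace(1e-6, 0.12, 200)
        np.testing.assert_allclose(c.tendon_inverse(c.tendon(e)), e, atol=1e-10)

    def test_force_velocity_inverse_roundtrip(self, curves):
        f = np.linspace(1e-6, 1.3999, 300)
        np.testing.assert_allclose(
            curves.force_velocity(curves.force_velocity_inverse(f)), f, atol=1e-10
        )

    def test_scalar_fast_paths_match_array_versions(self, curves):
        # same formulas and constants; agreement to 1-2 ulp (libm vs numpy)
        tol = dict(rel=5e-16, abs=5e-16)
        for l in np.linspace(0.3, 2.2, 57):
            assert curves.active_fl_scalar(l) == pytest.approx(
                float(curves.active_fl(l)), **tol)
            assert curves.passive_fl_scalar(l) == pytest.approx(
                float(curves.passive_fl(l)), **tol)
        for e in np.linspace(-0.02, 0.15, 57):
            assert curves.tendon_scalar(e) == pytest.approx(
                float(curves.tendon(e)), **tol)
        for v in np.linspace(-1.2, 3.0, 57):
            assert curves.force_velocity_scalar(v) == pytest.approx(
                float(curves.force_velocity(v)), **tol)
        for f in np.linspace(0.0, 1.5, 57):
            assert curves.force_velocity_inverse_scalar(f) == pytest.approx(
                float(curves.force_velocity_inverse(f)), **tol)


class TestPennation:
    def test_zero_pennation_stays_zero(self):
        for L_M in (0.01, 0.1, 1.0):
            assert pennation_angle(L_M, 0.1, 0.0) == 0.0

    def test_identity_at_optimal_length(self):
        a = math.radians(30.0)
        assert pennation_angle(0.1, 0.1, a) == pytest.approx(a, abs=1e-12)

    def test_constant_height_at_double_length(self):
        # sin(alpha) = L_o sin(30 deg) / (2 L_o) = 0.25
        a = pennation_angle(0.2, 0.1, math.radians(30.0))
        assert a == pytest.approx(math.asin(0.25), abs=1e-12)
        assert math.degrees(a) == pytest.approx(14.4775, abs=1e-3)

    def test_clamped_at_84_degrees(self):
        a = pennation_angle(1e-9, 0.1, math.radians(30.0))
        assert a == pytest.approx(math.radians(84.0), abs=1e-12)


class TestRigidTendon:
    def test_unpennated_identity(self):
        u = rigid_unit(alpha_o=0.0, L_o=0.1, L_s=0.03)
        assert rigid_tendon_fiber_length(0.03 + 0.1, u) == pytest.approx(0.1)

    def test_constant_height_identity(self):
        a = math.radians(30.0)
        u = rigid_unit(alpha_o=a, L_o=0.1, L_s=0.03)
        L_MT = 0.03 + 0.1 * math.cos(a)
        assert rigid_tendon_fiber_length(L_MT, u) == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_input_floors_fiber(self):
        u = rigid_unit(alpha_o=0.0, L_o=0.1, L_s=0.03)
        assert rigid_tendon_fiber_length(0.03, u) == pytest.approx(0.001)


class TestStaticEquilibrium:
    def test_constructed_fixed_point(self, curves):
        # alpha_o = 0, fiber at optimal length: muscle side is a*f_L(1) = a,
        # so the tendon strain must be tendon_inverse(a)
        u = compliant_unit(alpha_o=0.0)
        for a in (0.05, 0.3, 1.0):
            eps = float(curves.tendon_inverse(a))
            L_MT = u.L_o + u.L_s * (1.0 + eps)
            st = static_equilibrium_fiber_length(L_MT, a, u, curves)
            assert st.L_M == pytest.approx(u.L_o, rel=1e-9)
            assert st.converged

    def test_equilibrium_residual(self, curves):
        u = compliant_unit()
        st = static_equilibrium_fiber_length(0.22, 0.7, u, curves)
        assert abs(st.F_T - st.F_M * math.cos(st.alpha)) < 1e-6 * u.F_o

    def test_lower_activation_gives_longer_fiber(self, curves):
        u = compliant_unit()
        L_MT = u.L_s * 1.02 + u.L_o
        lo = static_equilibrium_fiber_length(L_MT, 0.05, u, curves)
        hi = static_equilibrium_fiber_length(L_MT, 1.0, u, curves)
        assert lo.L_M >= hi.L_M

    def test_rigid_mode_ignores_activation(self, curves):
        u = rigid_unit()
        L_MT = u.L_s + 1.1 * u.L_o
        expected = rigid_tendon_fiber_length(L_MT, u)
        for a in (0.05, 0.5, 1.0):
            st = static_equilibrium_fiber_length(L_MT, a, u, curves)
            assert st.L_M == expected

    def test_unbracketed_case_flagged(self, curves):
        # MTU shorter than the slack length: tendon force is identically 0
        # but passive fiber force is 0 too at short lengths -> no root
        u = compliant_unit(alpha_o=0.0)
        st = static_equilibrium_fiber_length(u.L_s * 0.5, 0.05, u, curves)
        assert not st.converged
        assert st.flag == "unbracketed"

    @settings(max_examples=60, deadline=None)
    @given(
        data=st.data(),
    )
    def test_randomized_solves_satisfy_equilibrium(self, curves, data):
        L_o = data.draw(st.floats(0.01, 0.2), label="L_o")
        ratio = data.draw(st.floats(0.55, 6.0), label="L_s_over_L_o")
        alpha_o = data.draw(st.floats(0.0, 0.45), label="alpha_o")
        a = data.draw(st.floats(0.05, 1.0), label="activation")
        stretch = data.draw(st.floats(0.7, 1.4), label="fiber_stretch")
        u = MuscleTendonUnit(
            name="r", F_o=100.0, L_o=L_o, V_max=10.0, alpha_o=alpha_o,
            L_s=ratio * L_o,
            path=[PathPoint("a", (0, 0, 0)), PathPoint("b", (1, 0, 0))],
        )
        L_MT = u.L_s + stretch * L_o * math.cos(alpha_o)
        st_ = static_equilibrium_fiber_length(L_MT, a, u, curves)
        if st_.converged:
            assert abs(st_.F_T - st_.F_M * math.cos(st_.alpha)) < 1e-6 * u.F_o


class TestSimulateFiberTrajectory:
    def test_constant_input_elastic_converges_to_static(self, curves):
        u = compliant_unit()
        L_MT = np.full(101, u.L_s * 1.01 + u.L_o * math.cos(u.alpha_o))
        traj = simulate_fiber_trajectory(u, curves, L_MT, 1.0, mode="elastic",
                                         cycle_duration=1.0)
        static = static_equilibrium_fiber_length(L_MT[0], 1.0, u, curves)
        # after the first 10 % of the cycle the fiber sits at equilibrium
        assert np.max(np.abs(traj.L_M[10:] - static.L_M)) < 1e-6

    def test_rigid_mode_is_activation_invariant(self, curves):
        u = rigid_unit()
        L_MT = u.L_s + u.L_o * (1.0 + 0.2 * np.sin(np.linspace(0, 2 * np.pi, 101)))
        lo = simulate_fiber_trajectory(u, curves, L_MT, 0.05)
        hi = simulate_fiber_trajectory(u, curves, L_MT, 1.0)
        assert lo.tendon_mode == hi.tendon_mode == "rigid"
        np.testing.assert_array_equal(lo.L_M, hi.L_M)

    def test_auto_mode_selection_follows_tendon_ratio(self, curves):
        L_MT_r = rigid_unit().L_s + rigid_unit().L_o * np.ones(101)
        assert simulate_fiber_trajectory(
            rigid_unit(), curves, L_MT_r, 1.0
        ).tendon_mode == "rigid"
        u = compliant_unit()
        L_MT_c = (u.L_s + u.L_o) * np.ones(101)
        assert simulate_fiber_trajectory(
            u, curves, L_MT_c, 1.0
        ).tendon_mode == "elastic"

    def test_elastic_tracks_static_on_slow_input(self, curves):
        # very compliant tendon (L_o/L_s = 0.2), slow sinusoidal input
        # (5 s cycle, amplitude 0.1 L_o): the dynamic solution stays within
        # 0.02 L_o of the quasi-static one.  At faster cadences the shallow
        # force-velocity curve produces genuine tracking lag, which is why
        # the elastic integrator exists alongside the static solver.
        u = compliant_unit(L_o=0.03, L_s=0.15, alpha_o=0.0)
        mid = u.L_s * 1.02 + u.L_o
        L_MT = mid + 0.1 * u.L_o * np.sin(np.linspace(0, 2 * np.pi, 101))
        for a in (0.05, 1.0):
            dyn = simulate_fiber_trajectory(
                u, curves, L_MT, a, mode="elastic", cycle_duration=5.0
            )
            stat = simulate_fiber_trajectory(u, curves, L_MT, a, mode="static")
            assert np.max(np.abs(dyn.L_M - stat.L_M)) < 0.02 * u.L_o

    def test_static_mode_matches_samplewise_solver(self, curves):
        u = compliant_unit()
        L_MT = u.L_s * 1.01 + u.L_o * (
            1.0 + 0.1 * np.sin(np.linspace(0, 2 * np.pi, 101))
        )
        traj = simulate_fiber_trajectory(u, curves, L_MT, 0.4, mode="static")
        for i in (0, 25, 50, 75, 100):
            st = static_equilibrium_fiber_length(L_MT[i], 0.4, u, curves)
            assert traj.L_M[i] == st.L_M

    def test_activation_is_floored(self, curves):
        u = compliant_unit()
        L_MT = (u.L_s + u.L_o) * np.ones(101)
        t0 = simulate_fiber_trajectory(u, curves, L_MT, 0.0, mode="static")
        t5 = simulate_fiber_trajectory(u, curves, L_MT, 0.05, mode="static")
        np.testing.assert_array_equal(t0.L_M, t5.L_M)
        assert t0.activation == 0.05

    def test_pointwise_activation_ordering_static(self, curves):
        u = compliant_unit()
        L_MT = u.L_s * 1.01 + u.L_o * (
            1.0 + 0.15 * np.sin(np.linspace(0, 2 * np.pi, 101))
        )
        lo = simulate_fiber_trajectory(u, curves, L_MT, 0.05, mode="static")
        hi = simulate_fiber_trajectory(u, curves, L_MT, 1.0, mode="static")
        assert np.all(lo.L_M >= hi.L_M)
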