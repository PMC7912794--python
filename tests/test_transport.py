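"""The charged-nanopore boundary-value solver and its closed-form limits."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import simpson

from nanosede import fixtures as fx
from nanosede.charge import ChargeProfile, average_charge, eval_profile, fit_midpoint_to_average
from nanosede.hindrance import bungay_brenner, neutral_rejection_curve
from nanosede.physchem import Species, make_solution
from nanosede.transport import (
    Membrane,
    OperatingPoint,
    enp_rhs,
    flux_conservation_residual,
    flux_from_pressure,
    partition_interface,
    solve_transport,
)

# idealized point-like 1:1 salt with equal diffusivities: Donnan closed forms
# become exact up to the (tiny) steric factor
NA0 = Species("cat", z=1, D_inf=1.33e-9, r_stokes=1e-15)
CL0 = Species("ani", z=-1, D_inf=1.33e-9, r_stokes=1e-15)


def salt_feed(c=10.0):
    return make_solution([NA0, CL0], {"cat": c, "ani": c})


def membrane(cloc=-20.0, rp=0.40e-9, dx=1e-4, eps_p=78.4, profile=None):
    prof = profile if profile is not None else ChargeProfile(cloc, cloc)
    return Membrane(rp=rp, dx_eff=dx, eps_p=eps_p, profile=prof)


def donnan_quadratic(c_eff_plus, c_eff_minus, X):
    """Closed-form 1:1 Donnan partition with net pore charge −CLoc = X."""
    u = (X + math.sqrt(X**2 + 4 * c_eff_plus * c_eff_minus)) / (2 * c_eff_plus)
    return c_eff_plus * u, c_eff_minus / u


class TestPartitionInterface:
    def test_no_exclusion_identity(self):
        feed = salt_feed(10.0)
        mem = membrane(cloc=0.0)
        pore, dpsi = partition_interface({"cat": 10.0, "ani": 10.0}, 0.0, mem, feed)
        assert dpsi == pytest.approx(0.0, abs=1e-12)
        # steric factor for the point-like test ions is (1-2.5e-6)^2
        assert pore["cat"] == pytest.approx(10.0, rel=2e-5)
        assert pore["ani"] == pytest.approx(10.0, rel=2e-5)

    def test_matches_quadratic_closed_form(self):
        feed = salt_feed(10.0)
        mem = membrane(cloc=-20.0)
        pore, dpsi = partition_interface({"cat": 10.0, "ani": 10.0}, -20.0, mem, feed)
        phi = (1 - 1e-15 / 0.40e-9) ** 2
        cp, cm = donnan_quadratic(10.0 * phi, 10.0 * phi, 20.0)
        assert pore["cat"] == pytest.approx(cp, rel=1e-8)
        assert pore["ani"] == pytest.approx(cm, rel=1e-8)
        assert cp == pytest.approx(24.142, abs=0.001)  # counterion enrichment
        assert dpsi < 0  # negative pore charge pulls the potential down

    def test_homogeneity_without_charge(self):
        feed = salt_feed(10.0)
        mem = membrane(cloc=0.0)
        p1, _ = partition_interface({"cat": 10.0, "ani": 10.0}, 0.0, mem, feed)
        p2, _ = partition_interface({"cat": 20.0, "ani": 20.0}, 0.0, mem, feed)
        assert p2["cat"] == pytest.approx(2 * p1["cat"], rel=1e-10)

    def test_unscreenable_charge_errors(self):
        neutral = Species("sugar", z=0, D_inf=6e-10, r_stokes=0.3e-9)
        feed = make_solution([neutral], {"sugar": 1.0})
        mem = membrane(cloc=-20.0)
        with pytest.raises((ValueError, RuntimeError)):
            partition_interface({"sugar": 1.0}, -20.0, mem, feed)


class TestEnpRhs:
    def test_neutral_solute_reduction(self):
        tracer = Species("tracer", z=0, D_inf=9.1e-10, r_stokes=0.2e-9)
        feed = make_solution([tracer], {"tracer": 1.0})
        mem = membrane(cloc=0.0)
        jv = 1e-5
        h = bungay_brenner(0.2e-9 / 0.40e-9)
        grad = enp_rhs(0.5, {"tracer": 2.0}, {"tracer": 0.5}, jv, mem, feed)
        A = jv * mem.dx_eff / (h.Kd * tracer.D_inf)
        assert grad["tracer"] == pytest.approx(A * (h.Kc * 2.0 - 0.5), rel=1e-10)

    def test_flat_steady_state_of_homogeneous_pore(self):
        # at c = c_permeate/Kc with no charge, all gradients vanish
        tracer = Species("tracer", z=0, D_inf=9.1e-10, r_stokes=0.2e-9)
        feed = make_solution([tracer], {"tracer": 1.0})
        mem = membrane(cloc=0.0)
        h = bungay_brenner(0.2e-9 / 0.40e-9)
        c_p = 0.4
        grad = enp_rhs(0.5, {"tracer": c_p / h.Kc}, {"tracer": c_p}, 1e-5, mem, feed)
        assert grad["tracer"] == pytest.approx(0.0, abs=1e-15)

    def test_field_sign_from_charge_gradient(self):
        # rising fixed charge with ions present pulls the scaled field negative
        from nanosede.transport import _TransportSystem

        feed = salt_feed(10.0)
        prof = ChargeProfile(c_entrance=-20.0, c_exit=20.0, x0=0.5, w=0.1)
        sys_ = _TransportSystem(membrane(profile=prof), feed, 1e-5)
        c = np.array([10.0, 10.0])
        ebar = sys_.field_scaled(0.5, c, sys_.Kc * c)  # convective term cancelled
        assert ebar < 0


class TestNeutralOracleEquivalence:
    @pytest.mark.parametrize("lam", [0.3, 0.5])
    def test_solver_matches_closed_form(self, lam):
        tracer = Species("tracer", z=0, D_inf=9.1e-10, r_stokes=lam * 0.40e-9)
        feed = make_solution([tracer], {"tracer": 1.0})
        mem = membrane(cloc=0.0)
        h = bungay_brenner(lam)
        for pe in (0.01, 0.3, 5.0, 50.0):
            jv = pe * h.Kd * tracer.D_inf / (h.Kc * mem.dx_eff)
            sol = solve_transport(mem, OperatingPoint(feed=feed, Jv=jv))
            assert sol.converged
            assert sol.rejection["tracer"] == pytest.approx(
                neutral_rejection_curve(lam, pe), abs=1e-6
            )


class TestSolveTransport:
    def test_zero_flux_equilibrium(self):
        sol = solve_transport(membrane(), OperatingPoint(feed=salt_feed(), Jv=0.0))
        assert sol.converged
        assert all(r == 0.0 for r in sol.rejection.values())

    def test_donnan_limiting_rejection(self):
        # high-Pe salt rejection by a homogeneous membrane approaches the
        # equilibrium-Donnan closed form 1 - 2c/sqrt(X^2 + 4c^2)
        c, X = 10.0, 20.0
        sol = solve_transport(
            membrane(cloc=-X), OperatingPoint(feed=salt_feed(c), Jv=1.3e-3)
        )
        r_lim = 1.0 - 2.0 * c / math.sqrt(X**2 + 4 * c**2)
        assert sol.rejection["cat"] == pytest.approx(r_lim, abs=2e-4)
        assert sol.rejection["cat"] == pytest.approx(sol.rejection["ani"], rel=1e-6)

    def test_grid_refinement_stability(self, feed):
        mem = fx.membrane("NF90")
        op = OperatingPoint(feed=feed, dP=1.2e6)
        r1 = solve_transport(mem, op, rtol=1e-8).rejection["SDZ"]
        r2 = solve_transport(mem, op, rtol=1e-9).rejection["SDZ"]
        assert abs(r1 - r2) <= 1e-6

    def test_electroneutrality_everywhere(self, fixture_solutions):
        for (name, jv), sol in fixture_solutions.items():
            cloc = eval_profile(sol.membrane.profile, sol.x_grid)
            resid = sol.conc["Na+"] - sol.conc["Cl-"] - sol.conc["SDZ"] + cloc
            scale = max(np.max(np.abs(c)) for c in sol.conc.values())
            assert np.max(np.abs(resid)) <= 1e-8 * scale, (name, jv)

    def test_species_flux_constant(self, fixture_solutions):
        for (name, jv), sol in fixture_solutions.items():
            assert flux_conservation_residual(sol) <= 1e-6, (name, jv)

    def test_born_removal_lowers_rejection(self, feed, membranes):
        for name, mem in membranes.items():
            no_born = replace(mem, eps_p=feed.eps_b)
            for jv in (0.6e-4, 6e-4):
                op = OperatingPoint(feed=feed, Jv=jv)
                with_b = solve_transport(mem, op, profiles=False).rejection["SDZ"]
                without = solve_transport(no_born, op, profiles=False).rejection["SDZ"]
                assert without < with_b, (name, jv)


class TestFieldMechanism:
    """Axial-field structure in the charge-gradient-dominated regime."""

    JV = 3e-4
    DX = 1e-4  # short effective thickness: the dCLoc/dx term sets the pit

    def _solve(self, feed, profile):
        mem = replace(fx.membrane("NF90", dx_eff=self.DX), profile=profile)
        return solve_transport(mem, OperatingPoint(feed=feed, Jv=self.JV))

    def test_bipolar_deeper_than_flat_at_equal_average(self, feed):
        bipolar = fx.membrane("NF90", dx_eff=self.DX).profile
        flat = ChargeProfile(average_charge(bipolar), average_charge(bipolar))
        pit_b = np.min(self._solve(feed, bipolar).E)
        pit_f = np.min(self._solve(feed, flat).E)
        assert pit_b < pit_f

    def test_pit_deepens_with_steepness(self, feed):
        pits = []
        for w in (0.12, 0.08, 0.05):
            p = fit_midpoint_to_average(
                ChargeProfile(-58.0, 50.0, x0=0.7, w=w), -25.8
            )
            pits.append(np.min(self._solve(feed, p).E))
        assert pits[0] > pits[1] > pits[2]

    def test_ion_profiles_swap_across_transition(self, fixture_solutions):
        for name in fx.MEMBRANE_NAMES:
            sol = fixture_solutions[(name, 6e-4)]
            x0 = sol.membrane.profile.x0
            before = np.searchsorted(sol.x_grid, max(x0 - 0.2, 0.05))
            after = np.searchsorted(sol.x_grid, min(x0 + 0.2, 0.98))
            assert sol.conc["Na+"][before] > sol.conc["Na+"][after], name
            assert sol.conc["Cl-"][after] > sol.conc["Cl-"][before], name

    def test_field_profile_recomputation(self, fixture_solutions):
        from nanosede.transport import electric_field_profile

        sol = fixture_solutions[("NF90", 3e-4)]
        x, e = electric_field_profile(sol)
        np.testing.assert_allclose(e, sol.E, rtol=1e-12)
        bad = replace(sol, converged=False)
        with pytest.raises(RuntimeError, match="unconverged"):
            electric_field_profile(bad)

    def test_potential_is_field_integral(self):
        # gentle conditions so the 401-point Simpson quadrature is accurate
        K = Species("cat", z=1, D_inf=1.96e-9, r_stokes=0.125e-9)
        Cl = Species("ani", z=-1, D_inf=2.03e-9, r_stokes=0.121e-9)
        feed = make_solution([K, Cl], {"cat": 10.0, "ani": 10.0})
        prof = ChargeProfile(c_entrance=-5.0, c_exit=5.0, x0=0.5, w=0.15)
        mem = Membrane(rp=1e-9, dx_eff=1e-5, eps_p=78.4, profile=prof)
        sol = solve_transport(mem, OperatingPoint(feed=feed, Jv=2e-4))
        drop = -simpson(sol.E, x=sol.x_grid) * mem.dx_eff
        assert drop == pytest.approx(sol.psi[-1] - sol.psi[0], rel=1e-6, abs=1e-12)


class TestFluxFromPressure:
    def test_hand_value(self):
        mem = Membrane(rp=0.34e-9, dx_eff=1e-6, eps_p=33.4,
                       profile=ChargeProfile(0.0, 0.0))
        empty = make_solution([], {})
        jv = flux_from_pressure(1e6, mem, empty, mu=0.89e-3)
        assert jv == pytest.approx((0.34e-9) ** 2 * 1e6 / (8 * 0.89e-3 * 1e-6), rel=1e-12)
        assert jv == pytest.approx(1.6e-5, rel=0.02)

    def test_limits(self):
        mem = Membrane(rp=0.34e-9, dx_eff=1e-6, eps_p=33.4,
                       profile=ChargeProfile(0.0, 0.0))
        empty = make_solution([], {})
        assert flux_from_pressure(0.0, mem, empty) == 0.0
        assert flux_from_pressure(2e6, mem, empty) == pytest.approx(
            2 * flux_from_pressure(1e6, mem, empty))


class TestOperatingPoint:
    def test_exactly_one_driver(self, feed):
        with pytest.raises(ValueError):
            OperatingPoint(feed=feed)
        with pytest.raises(ValueError):
            OperatingPoint(feed=feed, Jv=1e-5, dP=1e6)

    def test_negative_rejected(self, feed):
        with pytest.raises(ValueError):
            OperatingPoint(feed=feed, Jv=-1e-5)
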