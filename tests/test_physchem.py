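"""Closed-form physico-chemical primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanosede.physchem import (
    CONSTANTS,
    Species,
    born_energy,
    debye_parameter,
    gouy_chapman_sigma,
    make_solution,
    neutralize_with,
    sdz_charge_fractions,
    sigma_to_cloc,
    steric_partition,
    stokes_einstein_radius,
)

K = Species("K+", z=1, D_inf=1.96e-9, r_stokes=0.125e-9)
CL = Species("Cl-", z=-1, D_inf=2.03e-9, r_stokes=0.121e-9)


def kcl(conc=1.0, T=298.15, eps_b=78.4):
    return make_solution([K, CL], {"K+": conc, "Cl-": conc}, T=T, eps_b=eps_b)


class TestStokesEinstein:
    @pytest.mark.parametrize(
        "D, expected_nm",
        [
            (6.14e-10, 0.40),   # sulfadiazine
            (9.1e-10, 0.270),   # direct evaluation; differs from assay-derived radii
        ],
    )
    def test_known_radii(self, D, expected_nm):
        r = stokes_einstein_radius(D, 298.15, 0.89e-3) * 1e9
        assert r == pytest.approx(expected_nm, abs=0.005)

    def test_inverse_proportionality_and_roundtrip(self):
        r1 = stokes_einstein_radius(6e-10, 298.15, 0.89e-3)
        r2 = stokes_einstein_radius(1.2e-9, 298.15, 0.89e-3)
        assert r1 == pytest.approx(2 * r2, rel=1e-12)
        # radius -> D -> radius
        D_back = CONSTANTS.kB * 298.15 / (6 * math.pi * 0.89e-3 * r1)
        assert stokes_einstein_radius(D_back, 298.15, 0.89e-3) == pytest.approx(r1, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            stokes_einstein_radius(-1e-10, 298.15, 0.89e-3)


class TestSpeciation:
    def test_half_dissociation_at_pKa2(self):
        assert sdz_charge_fractions(6.50)[2] == pytest.approx(0.5, abs=2e-3)

    def test_anionic_fraction_at_ph7(self):
        # 1/(1+10^(6.5-7)) with a negligible cationic term
        assert sdz_charge_fractions(7.0)[2] == pytest.approx(0.760, abs=0.001)

    def test_acid_limit_is_cationic(self):
        assert sdz_charge_fractions(-5.0)[0] == pytest.approx(1.0, abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 14.0))
    def test_fractions_sum_to_one(self, pH):
        assert sum(sdz_charge_fractions(pH)) == pytest.approx(1.0, abs=1e-12)


class TestGouyChapman:
    def test_zero_zeta_zero_sigma(self):
        assert gouy_chapman_sigma(0.0, kcl()) == 0.0

    def test_thermal_voltage_value(self):
        # 1 mM KCl, zeta = -RT/F: direct evaluation of the closed form
        zeta = -CONSTANTS.R * 298.15 / CONSTANTS.F
        sigma = gouy_chapman_sigma(zeta, kcl(1.0))
        expected = -math.sqrt(
            2 * CONSTANTS.eps0 * 78.4 * CONSTANTS.R * 298.15
            * (1.0 * (math.e - 1) + 1.0 * (math.exp(-1) - 1))
        )
        assert sigma == pytest.approx(expected, rel=1e-12)
        assert abs(sigma) == pytest.approx(1.93e-3, rel=0.005)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(1e-4, 0.15))
    def test_odd_in_zeta(self, zeta):
        sol = kcl()
        assert gouy_chapman_sigma(-zeta, sol) == pytest.approx(
            -gouy_chapman_sigma(zeta, sol), rel=1e-12
        )

    def test_monotone_in_zeta_magnitude(self):
        sol = kcl()
        vals = [gouy_chapman_sigma(z, sol) for z in np.linspace(1e-3, 0.1, 25)]
        assert np.all(np.diff(vals) > 0)

    def test_debye_huckel_linearization(self):
        # sigma ~ eps0*eps_b*kappa*zeta within 2% for |zeta| <= 5 mV
        sol = kcl(10.0)
        kappa = debye_parameter(sol)
        for zeta in (-5e-3, -2e-3, 2e-3, 5e-3):
            lin = CONSTANTS.eps0 * 78.4 * kappa * zeta
            assert gouy_chapman_sigma(zeta, sol) == pytest.approx(lin, rel=0.02)


class TestChargeConversions:
    def test_sigma_to_cloc_value(self):
        # 2*sigma/(F*rp) by hand
        assert sigma_to_cloc(-1.93e-3, 0.35e-9) == pytest.approx(-114.3, rel=0.005)

    def test_sigma_to_cloc_scalings(self):
        assert sigma_to_cloc(0.0, 1e-9) == 0.0
        assert sigma_to_cloc(1e-3, 2e-9) == pytest.approx(sigma_to_cloc(1e-3, 1e-9) / 2)
        with pytest.raises(ValueError):
            sigma_to_cloc(1e-3, 0.0)


class TestBorn:
    SDZ = Species("SDZ", z=-1, D_inf=6.14e-10, r_stokes=0.40e-9)

    def test_no_contrast_and_neutral(self):
        assert born_energy(self.SDZ, 78.4, 78.4) == pytest.approx(0.0, abs=1e-15)
        neutral = Species("urea", z=0, D_inf=1.4e-9, r_stokes=0.2e-9)
        assert born_energy(neutral, 33.4, 78.4) == 0.0

    def test_sdz_in_nf90_pore(self):
        # prefactor e^2/(8 pi eps0 kB T r_cav) ~ 70.1 kT at r_cav = 0.40 nm
        w = born_energy(self.SDZ, 33.4, 78.4, 298.15)
        assert w == pytest.approx(1.20, abs=0.01)
        assert math.exp(-w) == pytest.approx(0.30, abs=0.01)

    def test_scales_with_z_squared(self):
        w1 = born_energy(self.SDZ, 33.4, 78.4)
        w2 = born_energy(self.SDZ.with_charge(-2), 33.4, 78.4)
        assert w2 == pytest.approx(4 * w1, rel=1e-12)

    def test_decreasing_in_pore_dielectric(self):
        ws = [born_energy(self.SDZ, ep, 78.4) for ep in np.linspace(10, 78.4, 20)]
        assert np.all(np.diff(ws) < 0)


class TestStericPartition:
    @pytest.mark.parametrize("lam, phi", [(0.0, 1.0), (0.5, 0.25)])
    def test_ferry(self, lam, phi):
        assert steric_partition(lam) == pytest.approx(phi)

    def test_cap_and_errors(self):
        with pytest.warns(UserWarning, match="capped"):
            capped = steric_partition(1.2, lambda_max=0.95)
        assert capped == pytest.approx((1 - 0.95) ** 2)
        with pytest.raises(ValueError):
            steric_partition(-0.1)


class TestSolutionState:
    def test_electroneutrality_enforced(self):
        with pytest.raises(ValueError, match="electroneutral"):
            make_solution([K, CL], {"K+": 2.0, "Cl-": 1.0})

    def test_neutralize_with(self):
        sdz = Species("SDZ", z=-1, D_inf=6.14e-10, r_stokes=0.4e-9)
        conc = neutralize_with([sdz, K, CL], {"SDZ": 0.004, "Cl-": 1.0}, "K+")
        assert conc["K+"] == pytest.approx(1.004)
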