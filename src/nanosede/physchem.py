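"""Physico-chemical primitives for charged-nanopore transport.

Closed forms used throughout the SEDE (steric + electric + dielectric
exclusion) pipeline: Stokes–Einstein sizing, amphoteric speciation,
Gouy–Chapman zeta-to-surface-charge conversion, surface↔volumetric fixed
charge, Born solvation penalties and Ferry steric partitioning.

All interfaces are SI (m, s, K, V, mol/m³, C/m²) unless a name says
otherwise; note 1 mol/m³ = 1 mmol/L.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "Species",
    "SolutionState",
    "stokes_einstein_radius",
    "sdz_charge_fractions",
    "gouy_chapman_sigma",
    "sigma_to_cloc",
    "born_energy",
    "steric_partition",
    "debye_parameter",
    "WATER_VISCOSITY_25C",
    "WATER_EPS_25C",
]

#: dynamic viscosity of water at 25 °C (Pa·s)
WATER_VISCOSITY_25C = 0.89e-3
#: bulk dielectric constant of water at 25 °C
WATER_EPS_25C = 78.4


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants used by the transport model."""

    F: float = 96485.33212  # Faraday constant, C/mol
    R: float = 8.314462618  # gas constant, J/(mol K)
    kB: float = 1.380649e-23  # Boltzmann constant, J/K
    e: float = 1.602176634e-19  # elementary charge, C
    eps0: float = 8.8541878128e-12  # vacuum permittivity, F/m
    N_A: float = 6.02214076e23  # Avogadro constant, 1/mol

    def __post_init__(self) -> None:
        for name in ("F", "R", "kB", "e", "eps0", "N_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be positive")
        if abs(self.F - self.e * self.N_A) > 1e-6 * self.F:
            raise ValueError("inconsistent constants: F != e * N_A")


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class Species:
    """A dissolved solute (ion or neutral molecule).

    Parameters
    ----------
    name : label used as key in feed/permeate maps.
    z : valence (0 for neutral solutes).
    D_inf : diffusivity at infinite dilution, m²/s.
    r_stokes : Stokes radius, m.
    r_cav : Born cavity radius, m. Defaults to ``r_stokes``.
    pKa1, pKa2 : optional acid dissociation constants (pKa1 < pKa2) for
        amphoteric solutes; used for speciation reporting only.
    """

    name: str
    z: int
    D_inf: float
    r_stokes: float
    r_cav: float | None = None
    pKa1: float | None = None
    pKa2: float | None = None

    def __post_init__(self) -> None:
        if self.D_inf <= 0:
            raise ValueError(f"{self.name}: D_inf must be positive")
        if self.r_stokes <= 0:
            raise ValueError(f"{self.name}: r_stokes must be positive")
        if self.r_cav is None:
            object.__setattr__(self, "r_cav", self.r_stokes)
        if self.r_cav <= 0:
            raise ValueError(f"{self.name}: r_cav must be positive")
        if self.pKa1 is not None and self.pKa2 is not None and not self.pKa1 < self.pKa2:
            raise ValueError(f"{self.name}: require pKa1 < pKa2")

    def with_charge(self, z: int) -> "Species":
        return replace(self, z=z)


@dataclass(frozen=True)
class SolutionState:
    """Bulk solution: temperature, dielectric constant, composition.

    ``bulk_conc`` maps species name → concentration in mol/m³. The feed must
    be electroneutral given the species valences supplied in ``species``.
    """

    T: float = 298.15
    eps_b: float = WATER_EPS_25C
    bulk_conc: dict[str, float] = field(default_factory=dict)
    species: tuple[Species, ...] = ()
    pH: float = 7.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.eps_b <= 1:
            raise ValueError("bulk dielectric constant must exceed 1")
        for name, c in self.bulk_conc.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")
        if self.species:
            net = sum(s.z * self.bulk_conc.get(s.name, 0.0) for s in self.species)
            if abs(net) > 1e-9:
                raise ValueError(f"feed not electroneutral: sum(z*c) = {net:g} mol/m^3")

    def conc(self, sp: Species) -> float:
        return self.bulk_conc.get(sp.name, 0.0)


def stokes_einstein_radius(D_inf: float, T: float, mu: float = WATER_VISCOSITY_25C) -> float:
    """Hydrodynamic (Stokes) radius from diffusivity, r = kB*T/(6*pi*mu*D)."""
    if D_inf <= 0 or T <= 0 or mu <= 0:
        raise ValueError("D_inf, T and mu must all be positive")
    return CONSTANTS.kB * T / (6.0 * math.pi * mu * D_inf)


def sdz_charge_fractions(pH: float, pKa1: float = 2.00, pKa2: float = 6.50) -> tuple[float, float, float]:
    """Cationic/neutral/anionic fractions of a diprotic amphoteric solute.

    Henderson–Hasselbalch speciation of H2A⁺ ⇌ HA ⇌ A⁻ (sulfadiazine-like):
    returns (f_cation, f_neutral, f_anion), summing to 1.
    """
    if not pKa1 < pKa2:
        raise ValueError("require pKa1 < pKa2")
    # Boltzmann-style weights relative to the neutral form
    w_cat = 10.0 ** (pKa1 - pH)
    w_neu = 1.0
    w_ani = 10.0 ** (pH - pKa2)
    tot = w_cat + w_neu + w_ani
    return w_cat / tot, w_neu / tot, w_ani / tot


def debye_parameter(solution: SolutionState) -> float:
    """Inverse Debye length κ (1/m) of the bulk solution."""
    c = CONSTANTS
    ionic = sum(
        sp.z**2 * solution.conc(sp) for sp in solution.species
    )  # mol/m^3, = 2*I
    return math.sqrt(c.F**2 * ionic / (c.eps0 * solution.eps_b * c.R * solution.T))


def gouy_chapman_sigma(zeta: float, solution: SolutionState) -> float:
    """Surface charge density (C/m²) from zeta potential via Gouy–Chapman.

    |σ| = sqrt(2 ε0 εb R T Σ_i c_i [exp(−z_i F ζ / R T) − 1]), with
    sign(σ) = sign(ζ). The sum is non-negative for any electroneutral bulk
    (each exp term is convex about ζ=0), so the square root is well defined.
    """
    if zeta == 0.0:
        return 0.0
    c = CONSTANTS
    arg = sum(
        solution.conc(sp) * math.expm1(-sp.z * c.F * zeta / (c.R * solution.T))
        for sp in solution.species
    )
    if arg < 0:
        if arg > -1e-12 * max(solution.bulk_conc.values(), default=1.0):
            arg = 0.0
        else:
            raise ArithmeticError(
                "negative Gouy–Chapman radicand; bulk composition not electroneutral?"
            )
    mag = math.sqrt(2.0 * c.eps0 * solution.eps_b * c.R * solution.T * arg)
    return math.copysign(mag, zeta)


def sigma_to_cloc(sigma: float, r_p: float) -> float:
    """Volumetric fixed charge (mol/m³) of a cylindrical pore, 2σ/(F·rp)."""
    if r_p <= 0:
        raise ValueError("pore radius must be positive")
    return 2.0 * sigma / (CONSTANTS.F * r_p)


def born_energy(species: Species, eps_p: float, eps_b: float, T: float = 298.15) -> float:
    """Born solvation penalty ΔW (units of kB·T) for entering the pore fluid.

    ΔW = (z e)² / (8 π ε0 kB T r_cav) · (1/εp − 1/εb). Zero for neutral
    solutes; positive when the pore dielectric constant is below bulk.
    """
    if eps_p <= 1 or eps_b <= 1:
        raise ValueError("dielectric constants must exceed 1")
    if species.z == 0:
        return 0.0
    c = CONSTANTS
    pref = (species.z * c.e) ** 2 / (8.0 * math.pi * c.eps0 * c.kB * T * species.r_cav)
    return pref * (1.0 / eps_p - 1.0 / eps_b)


#: default cap on rs/rp used where the Ferry picture breaks down (λ ≥ 1);
#: sits above the largest sub-unity λ occurring in the bundled membrane set.
DEFAULT_LAMBDA_MAX = 0.98


def effective_lambda(lambda_: float, lambda_max: float = DEFAULT_LAMBDA_MAX) -> float:
    """Cap λ = rs/rp at ``lambda_max``, warning when the cap bites.

    The Ferry/hindered-transport picture is only valid for λ < 1; real
    membranes still pass solutes nominally larger than the mean pore
    (pore-size dispersity, pore swelling), so oversized solutes are modelled
    at a capped λ rather than rejected absolutely.
    """
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    if lambda_ > lambda_max:
        warnings.warn(
            f"lambda={lambda_:.3f} capped to {lambda_max} (solute comparable to pore)",
            stacklevel=2,
        )
        return lambda_max
    return lambda_


def steric_partition(lambda_: float, lambda_max: float = DEFAULT_LAMBDA_MAX) -> float:
    """Ferry steric partition coefficient φ = (1−λ)², with λ capped."""
    lam = effective_lambda(lambda_, lambda_max)
    return (1.0 - lam) ** 2


def make_solution(
    species: list[Species],
    conc: dict[str, float],
    T: float = 298.15,
    eps_b: float = WATER_EPS_25C,
    pH: float = 7.0,
) -> SolutionState:
    """Convenience constructor; validates electroneutrality."""
    return SolutionState(T=T, eps_b=eps_b, bulk_conc=dict(conc), species=tuple(species), pH=pH)


def neutralize_with(
    species: list[Species], conc: dict[str, float], counter: str
) -> dict[str, float]:
    """Top up ``counter`` so that Σ z_i c_i = 0; returns a new concentration map."""
    by_name = {s.name: s for s in species}
    if counter not in by_name or by_name[counter].z == 0:
        raise ValueError("counterion must be a charged species in the list")
    out = dict(conc)
    net = sum(by_name[n].z * c for n, c in out.items() if n != counter)
    net += by_name[counter].z * out.get(counter, 0.0)
    delta = -net / by_name[counter].z
    new = out.get(counter, 0.0) + delta
    if new < -1e-12:
        raise ValueError("cannot electroneutralize: counterion would be negative")
    out[counter] = max(new, 0.0)
    return out
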