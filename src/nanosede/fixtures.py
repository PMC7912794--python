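"""Bundled study fixtures: solutes, tracers and the four membranes.

Solute properties (sulfadiazine, background ions, neutral tracers), the
per-membrane pore radii and pore dielectric constants from tracer
characterization, and bipolar fixed-charge profiles consistent with the
membranes' zeta-potential orderings and axially averaged charges.

Charge-profile plateau magnitudes are package calibrations: the entrance
(negative, carboxylate) magnitudes are ordered NF270 > TMN20H-400 > NF90 >
VNF2-8040 and the exit (positive, amine) magnitudes NF90 > TMN20H-400 >
VNF2-8040 > NF270, with NF90 and TMN20H-400 sharing nearly the same
entrance density; the transition midpoint of each profile is fitted so the
axial average matches the membrane's reported mean fixed charge.
"""

from __future__ import annotations

from functools import lru_cache

from .charge import ChargeProfile, fit_midpoint_to_average
from .physchem import Species, SolutionState, make_solution, neutralize_with
from .transport import Membrane

__all__ = [
    "SDZ",
    "NA",
    "CL",
    "TRACERS",
    "MEMBRANE_NAMES",
    "membrane",
    "default_feed",
    "TABLE_PORE_RADII_NM",
    "TABLE_LAMBDA",
    "ZETA_ENDPOINTS_MV",
    "IEP",
]

# Sulfadiazine: amphoteric sulfonamide, mono-anionic at pH 7 (pKa 2.00/6.50).
# The diffusivity is the value consistent with the 0.40 nm Stokes radius.
SDZ = Species("SDZ", z=-1, D_inf=6.14e-10, r_stokes=0.40e-9, pKa1=2.00, pKa2=6.50)
#: alternative literature diffusivity sometimes quoted for SDZ (m²/s)
SDZ_D_ALT = 0.605e-9

NA = Species("Na+", z=+1, D_inf=1.33e-9, r_stokes=0.184e-9)
CL = Species("Cl-", z=-1, D_inf=2.03e-9, r_stokes=0.121e-9)

#: neutral organic tracers used for pore-size characterization
TRACERS = (
    Species("dioxane", z=0, D_inf=9.1e-10, r_stokes=0.234e-9),
    Species("erythritol", z=0, D_inf=8.1e-10, r_stokes=0.263e-9),
    Species("xylose", z=0, D_inf=7.4e-10, r_stokes=0.290e-9),
)

MEMBRANE_NAMES = ("NF90", "NF270", "VNF2-8040", "TMN20H-400")

#: per-tracer λ = rs/rp from the characterization study, by membrane
TABLE_LAMBDA = {
    "NF90": {"dioxane": 0.691, "erythritol": 0.790, "xylose": 0.820},
    "NF270": {"dioxane": 0.509, "erythritol": 0.584, "xylose": 0.829},
    "VNF2-8040": {"dioxane": 0.616, "erythritol": 0.731, "xylose": 0.935},
    "TMN20H-400": {"dioxane": 0.498, "erythritol": 0.598, "xylose": 0.707},
}

#: mean pore radius (nm) and pore dielectric constant per membrane
TABLE_PORE_RADII_NM = {"NF90": 0.34, "NF270": 0.42, "VNF2-8040": 0.35, "TMN20H-400": 0.44}
PORE_EPS = {"NF90": 33.4, "NF270": 35.7, "VNF2-8040": 33.7, "TMN20H-400": 36.4}

#: isoelectric points of the four membranes
IEP = {"NF90": 4.25, "NF270": 3.18, "VNF2-8040": 4.26, "TMN20H-400": 3.92}

#: (zeta at pH 2, zeta at pH 9) in mV — encode the measured orderings:
#: pH 2 (amine): NF90 > TMN20H-400 > NF270 > VNF2-8040;
#: pH 9 (carboxyl, magnitude): NF270 > TMN20H-400 > VNF2-8040 ≈ NF90
ZETA_ENDPOINTS_MV = {
    "NF90": (35.0, -28.0),
    "NF270": (22.0, -55.0),
    "VNF2-8040": (20.0, -25.0),
    "TMN20H-400": (30.0, -40.0),
}

#: bipolar charge plateaus (mol/m³ = mmol/L) and target axial averages
CHARGE_PLATEAUS = {
    "NF90": (-58.0, 50.0),
    "NF270": (-62.0, 24.0),
    "VNF2-8040": (-45.0, 25.0),
    "TMN20H-400": (-60.0, 40.0),
}
CHARGE_AVERAGES = {"NF90": -25.8, "NF270": -30.0, "VNF2-8040": -33.0, "TMN20H-400": -33.0}

#: lumped effective active-layer thickness Δw/Ak (m); calibrated so the
#: convective term of the axial field dominates over the charge-gradient term
#: at the reference flux window (order-of-magnitude pit deepening per decade
#: of Jv), as observed for these membranes
DEFAULT_DX_EFF = 1.0e-2

#: default transition width of the charge step
DEFAULT_W = 0.08


@lru_cache(maxsize=None)
def charge_profile(name: str, w: float = DEFAULT_W) -> ChargeProfile:
    """Calibrated bipolar profile for one bundled membrane."""
    c_ent, c_exit = CHARGE_PLATEAUS[name]
    prof = ChargeProfile(c_entrance=c_ent, c_exit=c_exit, x0=0.65, w=w)
    return fit_midpoint_to_average(prof, CHARGE_AVERAGES[name])


@lru_cache(maxsize=None)
def membrane(name: str, dx_eff: float = DEFAULT_DX_EFF) -> Membrane:
    """One of the four bundled membranes, fully parameterized."""
    if name not in MEMBRANE_NAMES:
        raise KeyError(f"unknown membrane {name!r}; choose from {MEMBRANE_NAMES}")
    return Membrane(
        rp=TABLE_PORE_RADII_NM[name] * 1e-9,
        dx_eff=dx_eff,
        eps_p=PORE_EPS[name],
        profile=charge_profile(name),
        name=name,
    )


def default_feed(
    sdz_conc: float = 4.0e-3,
    background_nacl: float = 1.0,
    T: float = 298.15,
    pH: float = 7.0,
) -> SolutionState:
    """Feed for SDZ runs: SDZ⁻ (4 µM ≙ 1 mg/L) + Na⁺ + NaCl background (mol/m³)."""
    species = [SDZ, NA, CL]
    conc = neutralize_with(species, {"SDZ": sdz_conc, "Cl-": background_nacl}, "Na+")
    return make_solution(species, conc, T=T, pH=pH)
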