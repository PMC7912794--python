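"""Bipolar axial fixed-charge distributions along a nanopore.

Polyamide active layers formed by interfacial polymerization carry
deprotonated carboxyls on the outer (feed) face and protonated amines on
the inner (permeate) face, so the volumetric fixed charge CLoc(x) runs
from a negative entrance plateau to a positive exit plateau. The profile
family here is a boundary-clamped logistic smooth step parameterized by
the two plateau values, a transition midpoint x0 and a width w; it is
smooth, monotone, and has an analytic derivative for the axial-field term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .physchem import SolutionState, gouy_chapman_sigma, sigma_to_cloc

__all__ = [
    "ChargeProfile",
    "ZetaCurve",
    "eval_profile",
    "profile_derivative",
    "average_charge",
    "fit_midpoint_to_average",
    "calibrate_profile",
]


@dataclass(frozen=True)
class ChargeProfile:
    """Smooth-step fixed-charge profile on the normalized pore axis x∈[0,1].

    ``c_entrance`` (mol/m³, typically ≤ 0) is the value exactly at x=0 and
    ``c_exit`` (typically ≥ 0) exactly at x=1; ``x0`` is the transition
    midpoint and ``w`` its width. ``c_entrance == c_exit`` degenerates to a
    homogeneous membrane.
    """

    c_entrance: float
    c_exit: float
    x0: float = 0.65
    w: float = 0.08
    form: str = "logistic-step"

    def __post_init__(self) -> None:
        if not 0.0 < self.x0 < 1.0:
            raise ValueError("transition midpoint x0 must lie in (0,1)")
        if self.w <= 0:
            raise ValueError("transition width w must be positive")

    # -- shape helpers -------------------------------------------------
    def _s(self, x):
        """Clamped logistic step: exactly 0 at x=0 and 1 at x=1."""
        s = _expit((np.asarray(x, dtype=float) - self.x0) / self.w)
        s0 = _expit(-self.x0 / self.w)
        s1 = _expit((1.0 - self.x0) / self.w)
        return (s - s0) / (s1 - s0)

    def _sprime(self, x):
        x = np.asarray(x, dtype=float)
        s = _expit((x - self.x0) / self.w)
        s0 = _expit(-self.x0 / self.w)
        s1 = _expit((1.0 - self.x0) / self.w)
        return s * (1.0 - s) / (self.w * (s1 - s0))

    def __call__(self, x):
        return eval_profile(self, x)

    def scaled(self, factor: float) -> "ChargeProfile":
        """Profile with both plateaus multiplied by ``factor`` (shape kept)."""
        return replace(self, c_entrance=self.c_entrance * factor, c_exit=self.c_exit * factor)


def _expit(t):
    return 0.5 * (1.0 + np.tanh(np.asarray(t, dtype=float) / 2.0))


@dataclass(frozen=True)
class ZetaCurve:
    """Measured zeta potential (V) versus pH, with an optional fitted IEP."""

    pH: tuple[float, ...]
    zeta: tuple[float, ...]
    iep: float | None = None

    def __post_init__(self) -> None:
        if len(self.pH) != len(self.zeta):
            raise ValueError("pH and zeta must have equal length")


def _check_x(x) -> np.ndarray:
    xa = np.asarray(x, dtype=float)
    if np.any(xa < -1e-12) or np.any(xa > 1.0 + 1e-12):
        raise ValueError("x must lie in [0, 1]")
    return np.clip(xa, 0.0, 1.0)


def eval_profile(profile: ChargeProfile, x):
    """CLoc(x) in mol/m³ on the normalized axis."""
    xa = _check_x(x)
    out = profile.c_entrance + (profile.c_exit - profile.c_entrance) * profile._s(xa)
    return out.item() if np.ndim(x) == 0 else out


def profile_derivative(profile: ChargeProfile, x):
    """dCLoc/dx (mol/m³ per unit normalized length); ≥ 0 for bipolar profiles."""
    xa = _check_x(x)
    out = (profile.c_exit - profile.c_entrance) * profile._sprime(xa)
    return out.item() if np.ndim(x) == 0 else out


def average_charge(profile: ChargeProfile) -> float:
    """Axially averaged fixed charge ∫₀¹ CLoc dx (mol/m³), adaptive quadrature."""
    val, _ = quad(lambda x: eval_profile(profile, x), 0.0, 1.0,
                  epsabs=1e-10, epsrel=1e-10, limit=200,
                  points=[profile.x0])
    return val


def fit_midpoint_to_average(profile: ChargeProfile, target_average: float) -> ChargeProfile:
    """Refit the transition midpoint x0 so ∫₀¹ CLoc dx equals ``target_average``."""
    lo = min(profile.c_entrance, profile.c_exit)
    hi = max(profile.c_entrance, profile.c_exit)
    if not lo <= target_average <= hi:
        raise ValueError(
            f"target average {target_average:g} outside attainable range [{lo:g}, {hi:g}]"
        )

    def resid(x0_try: float) -> float:
        return average_charge(replace(profile, x0=x0_try)) - target_average

    eps = 1e-6
    r_lo, r_hi = resid(eps), resid(1.0 - eps)
    if r_lo * r_hi > 0:
        x0_fit = eps if abs(r_lo) < abs(r_hi) else 1.0 - eps
    else:
        x0_fit = brentq(resid, eps, 1.0 - eps, xtol=1e-12)
    return replace(profile, x0=x0_fit)


def calibrate_profile(
    zeta_acid: float,
    zeta_base: float,
    rp: float,
    solution: SolutionState,
    target_average: float | None = None,
    x0: float = 0.65,
    w: float = 0.08,
) -> ChargeProfile:
    """Build a bipolar profile from acid/base zeta potentials.

    The strong-base zeta (carboxylate-dominated, negative) sets the feed-side
    entrance plateau via Gouy–Chapman + the surface→volume conversion
    2σ/(F·rp); the strong-acid zeta (protonated amine, positive) sets the
    exit plateau. When ``target_average`` is given, the transition midpoint
    x0 is refitted so the axial average matches it.
    """
    if not (zeta_base < 0.0 < zeta_acid):
        raise ValueError("amphoteric membrane requires zeta_base < 0 < zeta_acid")
    c_ent = sigma_to_cloc(gouy_chapman_sigma(zeta_base, solution), rp)
    c_exit = sigma_to_cloc(gouy_chapman_sigma(zeta_acid, solution), rp)
    prof = ChargeProfile(c_entrance=c_ent, c_exit=c_exit, x0=x0, w=w)
    if target_average is None:
        return prof
    return fit_midpoint_to_average(prof, target_average)
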