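"""Hydrodynamic hindrance in cylindrical pores (Bungay–Brenner).

Centerline-approximation hindrance factors for diffusion (Kd) and
convection (Kc) of a sphere in a long cylindrical pore, valid over the
whole λ = rs/rp ∈ [0, 1) range, plus the closed-form rejection law for a
neutral solute in hindered convection–diffusion. The closed form doubles
as an independent oracle for the full charged-pore solver in its neutral
limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HindranceFactors",
    "bungay_brenner",
    "neutral_limiting_rejection",
    "neutral_rejection_curve",
    "KT_COEFFS",
    "KS_COEFFS",
]

# Seven-coefficient series for the axial drag (Kt) and shear (Ks)
# resistance of a sphere on the centerline of a cylindrical pore.
# K = (9/4)π²√2 (1−λ)^{-5/2} [1 + a1(1−λ) + a2(1−λ)²] + a3 + a4λ + a5λ² + a6λ³ + a7λ⁴
KT_COEFFS = (-73.0 / 60.0, 77293.0 / 50400.0, -22.5083, -5.6117, -0.3363, -1.216, 1.647)
KS_COEFFS = (7.0 / 60.0, -2227.0 / 50400.0, 4.0180, -3.9788, -1.9215, 4.392, 5.006)


@dataclass(frozen=True)
class HindranceFactors:
    """Hindrance set at a given λ: steric partition φ, diffusive Kd, convective Kc."""

    lambda_: float
    phi: float
    Kd: float
    Kc: float


def _series(lambda_: float, coeffs: tuple[float, ...]) -> float:
    a1, a2, a3, a4, a5, a6, a7 = coeffs
    u = 1.0 - lambda_
    lead = (9.0 / 4.0) * math.pi**2 * math.sqrt(2.0) * u ** (-2.5) * (1.0 + a1 * u + a2 * u * u)
    poly = a3 + lambda_ * (a4 + lambda_ * (a5 + lambda_ * (a6 + lambda_ * a7)))
    return lead + poly


def bungay_brenner(lambda_: float) -> HindranceFactors:
    """Bungay–Brenner hindrance factors at λ = rs/rp.

    Kd = 6π/Kt and Kc = (2−φ)·Ks/(2·Kt), with φ = (1−λ)². Callers are
    responsible for capping λ (see ``physchem.effective_lambda``); λ ≥ 1 is
    a domain error here.
    """
    if not 0.0 <= lambda_ < 1.0:
        raise ValueError("lambda must lie in [0, 1); cap oversized solutes first")
    Kt = _series(lambda_, KT_COEFFS)
    Ks = _series(lambda_, KS_COEFFS)
    phi = (1.0 - lambda_) ** 2
    Kd = 6.0 * math.pi / Kt
    Kc = (2.0 - phi) * Ks / (2.0 * Kt)
    return HindranceFactors(lambda_=lambda_, phi=phi, Kd=Kd, Kc=Kc)


def neutral_limiting_rejection(lambda_: float) -> float:
    """Infinite-Péclet rejection of a neutral solute, R∞ = 1 − φ·Kc."""
    f = bungay_brenner(lambda_)
    return 1.0 - f.phi * f.Kc


def neutral_rejection_curve(lambda_: float, peclet):
    """Rejection of a neutral solute at finite pore Péclet number.

    R = 1 − φKc / (1 − (1−φKc) e^{−Pe}), Pe = Kc·Jv·Δx_eff/(Kd·D). Vectorized
    over ``peclet``; R(0)=0 and R(∞)=1−φKc.
    """
    pe = np.asarray(peclet, dtype=float)
    if np.any(pe < 0):
        raise ValueError("Peclet number must be non-negative")
    f = bungay_brenner(lambda_)
    pk = f.phi * f.Kc
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - (1.0 - pk) * np.exp(-pe)
        r = np.where(pe == 0, 0.0, 1.0 - pk / denom)
    return r.item() if np.isscalar(peclet) or np.ndim(peclet) == 0 else r
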