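"""Pore-size and pore-dielectric characterization from neutral tracers.

A membrane's mean pore radius is estimated from the rejection of small
neutral organics (dioxane, erythritol, xylose): the infinite-Péclet
limiting rejection of a neutral solute depends only on λ = rs/rp through
R∞ = 1 − φ·Kc, so each tracer's limiting rejection inverts to a λ, each λ
gives rp = rs/λ, and the per-tracer radii are averaged. The pore
dielectric constant is assigned per membrane from a configured table
(with a pluggable εp(rp) correlation hook).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit
from sklearn.base import BaseEstimator

from .hindrance import neutral_limiting_rejection, neutral_rejection_curve
from .physchem import Species

__all__ = [
    "TracerObservation",
    "PoreEstimate",
    "limiting_rejection_from_curve",
    "invert_lambda",
    "pore_radius_from_lambda",
    "average_pore_radius",
    "assign_pore_dielectric",
    "PoreSizeEstimator",
    "PORE_DIELECTRIC_TABLE",
]

#: per-membrane pore dielectric constants (confined-water values)
PORE_DIELECTRIC_TABLE = {
    "NF90": 33.4,
    "NF270": 35.7,
    "VNF2-8040": 33.7,
    "TMN20H-400": 36.4,
}

#: largest λ the inversion will return; beyond it R∞(λ) is extrapolated flat
LAMBDA_INVERT_MAX = 0.95


@dataclass(frozen=True)
class TracerObservation:
    """Observed rejection-vs-flux curve for one neutral tracer."""

    tracer: Species
    fluxes: tuple[float, ...]
    rejections: tuple[float, ...]
    limiting_rejection: float | None = None

    def __post_init__(self) -> None:
        if len(self.fluxes) != len(self.rejections):
            raise ValueError("fluxes and rejections must have equal length")
        fl = np.asarray(self.fluxes)
        if len(fl) and np.any(np.diff(fl) <= 0):
            raise ValueError("fluxes must be strictly increasing")
        rj = np.asarray(self.rejections)
        if len(rj) and (np.any(rj < 0) or np.any(rj >= 1)):
            raise ValueError("rejections must lie in [0, 1)")


@dataclass(frozen=True)
class PoreEstimate:
    """Characterization result: per-tracer λ and rp, their mean, and εp."""

    per_tracer_lambda: dict[str, float]
    per_tracer_rp: dict[str, float]  # metres
    rp_mean: float  # metres
    eps_p: float | None = None


def limiting_rejection_from_curve(
    obs: TracerObservation, strategy: str = "fit"
) -> float:
    """Infinite-Péclet rejection extracted from a rejection-vs-flux curve.

    ``strategy='fit'`` (default) fits the two-parameter neutral hindered
    transport law R(Jv) = R(λ, Pe = k·Jv) over the whole curve and returns
    the fitted plateau 1 − φKc. ``strategy='plateau'`` averages the two
    highest-flux points.
    """
    if obs.limiting_rejection is not None:
        return obs.limiting_rejection
    fl = np.asarray(obs.fluxes, dtype=float)
    rj = np.asarray(obs.rejections, dtype=float)
    if len(fl) < 4 or fl[-1] < 5.0 * fl[0]:
        raise ValueError("need >=4 flux points spanning at least a 5x range")
    if np.any(np.diff(rj) < -0.05 * max(rj.max(), 1e-9)):
        warnings.warn("rejection curve non-monotone beyond noise tolerance", stacklevel=2)
    if strategy == "plateau":
        return float(np.mean(rj[-2:]))
    if strategy != "fit":
        raise ValueError(f"unknown strategy {strategy!r}")
    if np.allclose(rj, 0.0, atol=1e-12):
        return 0.0

    def model(jv, lam, k):
        return neutral_rejection_curve(lam, k * jv)

    lam0 = min(invert_lambda(float(np.clip(rj[-1], 0.0, 0.99))), 0.9) or 0.3
    k0 = 1.0 / np.median(fl)
    try:
        popt, _ = curve_fit(
            model, fl, rj, p0=[max(lam0, 0.05), k0],
            bounds=([1e-6, 1e-12], [LAMBDA_INVERT_MAX, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise RuntimeError(f"limiting-rejection fit failed: {exc}") from exc
    return neutral_limiting_rejection(popt[0])


def invert_lambda(R_inf: float) -> float:
    """Unique λ ∈ [0, 0.95] with neutral limiting rejection equal to ``R_inf``.

    R∞(λ) = 1 − φ·Kc is strictly increasing on this range, so a bracketed
    root search suffices. Values above R∞(0.95) are capped with a warning.
    """
    if not 0.0 <= R_inf < 1.0:
        raise ValueError("limiting rejection must lie in [0, 1)")
    if R_inf == 0.0:
        return 0.0
    r_cap = neutral_limiting_rejection(LAMBDA_INVERT_MAX)
    if R_inf >= r_cap:
        warnings.warn(
            f"limiting rejection {R_inf:.4f} exceeds R_inf({LAMBDA_INVERT_MAX}); capping lambda",
            stacklevel=2,
        )
        return LAMBDA_INVERT_MAX
    return brentq(
        lambda lam: neutral_limiting_rejection(lam) - R_inf,
        0.0, LAMBDA_INVERT_MAX, xtol=1e-12,
    )


def pore_radius_from_lambda(lambda_: float, r_stokes: float) -> float:
    """Pore radius rp = rs/λ (metres in, metres out)."""
    if lambda_ <= 0:
        raise ValueError("lambda must be positive (lambda=0 implies an infinite pore)")
    return r_stokes / lambda_


def average_pore_radius(radii) -> float:
    """Arithmetic mean pore radius across tracers (same units in and out)."""
    radii = list(radii)
    if not radii:
        raise ValueError("no pore-radius estimates to average")
    return float(np.mean(radii))


def assign_pore_dielectric(
    rp: float,
    membrane: str | None = None,
    table: dict[str, float] | None = None,
    correlation=None,
) -> float:
    """Pore dielectric constant: table lookup by membrane, or an εp(rp) hook."""
    if rp <= 0:
        raise ValueError("pore radius must be positive")
    if correlation is not None:
        return float(correlation(rp))
    table = PORE_DIELECTRIC_TABLE if table is None else table
    if membrane is None or membrane not in table:
        raise KeyError(
            f"membrane {membrane!r} not in dielectric table and no correlation supplied"
        )
    return table[membrane]


class PoreSizeEstimator(BaseEstimator):
    """Estimate a membrane's mean pore radius from neutral-tracer rejections.

    Parameters
    ----------
    strategy : 'fit' or 'plateau'
        How the limiting rejection is extracted from each tracer curve.
    membrane : optional label used for the dielectric-constant table lookup.
    dielectric_table, dielectric_correlation : see ``assign_pore_dielectric``.

    Attributes (after ``fit``)
    --------------------------
    lambda_per_tracer_ : dict name → λ
    rp_per_tracer_m_ : dict name → radius (m)
    rp_m_ : mean pore radius (m); ``rp_nm_`` is the same in nm
    eps_p_ : assigned pore dielectric constant (None if not resolvable)
    """

    def __init__(self, strategy: str = "fit", membrane: str | None = None,
                 dielectric_table: dict[str, float] | None = None,
                 dielectric_correlation=None):
        self.strategy = strategy
        self.membrane = membrane
        self.dielectric_table = dielectric_table
        self.dielectric_correlation = dielectric_correlation

    def fit(self, observations, y=None):
        """``observations``: iterable of TracerObservation (y is ignored)."""
        obs = list(observations)
        if not obs:
            raise ValueError("need at least one tracer observation")
        self.lambda_per_tracer_ = {}
        self.rp_per_tracer_m_ = {}
        for o in obs:
            r_inf = limiting_rejection_from_curve(o, strategy=self.strategy)
            lam = invert_lambda(r_inf)
            self.lambda_per_tracer_[o.tracer.name] = lam
            self.rp_per_tracer_m_[o.tracer.name] = pore_radius_from_lambda(
                lam, o.tracer.r_stokes
            )
        self.rp_m_ = average_pore_radius(self.rp_per_tracer_m_.values())
        self.rp_nm_ = self.rp_m_ * 1e9
        try:
            self.eps_p_ = assign_pore_dielectric(
                self.rp_m_, membrane=self.membrane,
                table=self.dielectric_table,
                correlation=self.dielectric_correlation,
            )
        except KeyError:
            self.eps_p_ = None
        return self

    def pore_estimate(self) -> PoreEstimate:
        """Fitted results bundled as a PoreEstimate record."""
        return PoreEstimate(
            per_tracer_lambda=dict(self.lambda_per_tracer_),
            per_tracer_rp=dict(self.rp_per_tracer_m_),
            rp_mean=self.rp_m_,
            eps_p=self.eps_p_,
        )
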