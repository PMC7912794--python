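"""Seeded generators for every input the analysis pipeline consumes.

Three generators mirror the three experimental data streams of a membrane
characterization campaign: neutral-tracer rejection curves (hindered
transport law + multiplicative noise), zeta-potential-vs-pH sigmoids
crossing zero at a prescribed isoelectric point, and SDZ
rejection-vs-pressure datasets produced by the forward SEDE model. All
noise is multiplicative lognormal on the transmission (1−R) so noisy
rejections remain in (−∞, 1); each generator is a pure function of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit, logit

from .characterization import TracerObservation
from .charge import ZetaCurve
from .hindrance import bungay_brenner, neutral_rejection_curve
from .physchem import Species, SolutionState, effective_lambda
from .transport import Membrane, OperatingPoint, solve_transport

__all__ = [
    "SyntheticSpec",
    "gen_tracer_rejections",
    "gen_zeta_curve",
    "gen_rejection_dataset",
    "fit_iep",
]


def _default_flux_grid(membrane: Membrane, tracers) -> tuple[float, ...]:
    """8 log-spaced fluxes spanning Pe ≈ 0.1–20 for the median tracer."""
    sp = sorted(tracers, key=lambda s: s.r_stokes)[len(tracers) // 2]
    lam = effective_lambda(sp.r_stokes / membrane.rp, membrane.lambda_max)
    h = bungay_brenner(lam)
    jv_unit = h.Kd * sp.D_inf / (h.Kc * membrane.dx_eff)  # Jv giving Pe = 1
    return tuple(np.geomspace(0.1, 20.0, 8) * jv_unit)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth + noise description for the synthetic campaign."""

    seed: int
    membrane_truth: Membrane
    tracer_set: tuple[Species, ...]
    flux_grid: tuple[float, ...] = ()
    noise_sigma: float = 0.02  # lognormal sigma on (1-R)
    zeta_truth: tuple[float, float, float, float] = (4.25, 0.035, -0.030, 0.8)
    # (iep, zeta_acid V, zeta_base V, sigmoid slope in pH units)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not self.flux_grid:
            object.__setattr__(
                self, "flux_grid",
                _default_flux_grid(self.membrane_truth, self.tracer_set),
            )


def _noisy_rejection(
    r: np.ndarray, sigma: float, rng: np.random.Generator, r_max: float = 0.999
) -> np.ndarray:
    """Multiplicative lognormal noise on transmission, clipped to [0, r_max].

    Because the noise acts on (1−R), a noisy rejection can never reach 1;
    the upper clip matters only for tracer curves, where it mimics the
    resolution limit of a concentration assay.
    """
    if sigma == 0.0:
        return np.clip(r, 0.0, r_max)
    t = (1.0 - r) * np.exp(rng.normal(0.0, sigma, size=r.shape))
    return np.clip(1.0 - t, 0.0, r_max)


def gen_tracer_rejections(spec: SyntheticSpec) -> list[TracerObservation]:
    """Noisy neutral-tracer rejection curves from the hindered-transport law."""
    rng = np.random.default_rng(spec.seed)
    mem = spec.membrane_truth
    jv = np.asarray(spec.flux_grid, dtype=float)
    out = []
    for sp in spec.tracer_set:
        lam = sp.r_stokes / mem.rp
        if lam >= 1.0:
            raise ValueError(f"tracer {sp.name} larger than the true pore")
        h = bungay_brenner(lam)
        pe = h.Kc * jv * mem.dx_eff / (h.Kd * sp.D_inf)
        r = np.asarray(neutral_rejection_curve(lam, pe))
        r = _noisy_rejection(r, spec.noise_sigma, rng)
        out.append(TracerObservation(tracer=sp, fluxes=tuple(jv), rejections=tuple(r)))
    return out


def tracer_table(spec: SyntheticSpec, membrane_name: str = "synthetic") -> pd.DataFrame:
    """Tidy CSV-shaped table of the synthetic tracer campaign."""
    rows = []
    for obs in gen_tracer_rejections(spec):
        for f, r in zip(obs.fluxes, obs.rejections):
            rows.append(
                {"membrane": membrane_name, "tracer": obs.tracer.name,
                 "flux_m_per_s": f, "rejection": r}
            )
    return pd.DataFrame(rows)


def _zeta_model(pH, iep, z_acid, z_base, slope):
    # logistic in pH pinned to zero exactly at the isoelectric point
    p0 = iep - slope * logit(z_acid / (z_acid - z_base))
    return z_acid + (z_base - z_acid) * expit((np.asarray(pH, float) - p0) / slope)


def gen_zeta_curve(
    spec: SyntheticSpec,
    pH_grid=None,
    sigma_zeta: float = 1e-3,
) -> ZetaCurve:
    """Sigmoidal zeta–pH curve crossing zero at the true IEP, plus noise (V)."""
    iep, z_acid, z_base, slope = spec.zeta_truth
    if not z_base < 0 < z_acid:
        raise ValueError("require zeta_base < 0 < zeta_acid")
    rng = np.random.default_rng(spec.seed + 1)
    pH = np.asarray(pH_grid if pH_grid is not None else np.linspace(2.0, 9.0, 15), float)
    zeta = _zeta_model(pH, iep, z_acid, z_base, slope)
    zeta = zeta + rng.normal(0.0, sigma_zeta, size=zeta.shape)
    return ZetaCurve(pH=tuple(pH), zeta=tuple(zeta), iep=None)


def fit_iep(curve: ZetaCurve) -> float:
    """Isoelectric point recovered by refitting the zeta–pH sigmoid."""
    pH = np.asarray(curve.pH)
    zeta = np.asarray(curve.zeta)
    p0 = [pH[np.argmin(np.abs(zeta))], max(zeta.max(), 1e-3),
          min(zeta.min(), -1e-3), 1.0]
    popt, _ = curve_fit(
        _zeta_model, pH, zeta, p0=p0,
        bounds=([pH.min(), 1e-4, -0.5, 0.05], [pH.max(), 0.5, -1e-4, 5.0]),
        maxfev=20000,
    )
    return float(popt[0])


def gen_rejection_dataset(
    spec: SyntheticSpec,
    solute: Species,
    pressures,
    feed: SolutionState = None,
) -> pd.DataFrame:
    """Noisy SDZ rejection-vs-pressure dataset from the forward SEDE model.

    Returns a table with columns dP_Pa, Jv_m_per_s, rejection (noisy) and
    rejection_true; the generating membrane (including its charge profile)
    is the recovery target.
    """
    from .fixtures import default_feed

    rng = np.random.default_rng(spec.seed + 2)
    feed = feed if feed is not None else default_feed()
    mem = spec.membrane_truth
    rows = []
    guess = None
    for dp in np.asarray(pressures, dtype=float):
        sol = solve_transport(
            mem, OperatingPoint(feed=feed, dP=float(dp)),
            rtol=1e-8, permeate_guess=guess, profiles=False,
        )
        if not sol.converged:
            raise RuntimeError(f"forward model failed to converge at dP={dp:g} Pa")
        guess = sol.permeate
        rows.append({"dP_Pa": dp, "Jv_m_per_s": sol.Jv,
                     "rejection_true": sol.rejection[solute.name]})
    df = pd.DataFrame(rows)
    df["rejection"] = _noisy_rejection(
        df["rejection_true"].to_numpy(), spec.noise_sigma, rng, r_max=1.0
    )
    return df[["dP_Pa", "Jv_m_per_s", "rejection", "rejection_true"]]
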