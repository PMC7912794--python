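"""Estimator-style front end for the SEDE transport model.

``SEDETransportModel`` wraps the boundary-value solver in the familiar
fit/predict shape: ``predict`` maps an array of transmembrane pressures (or
volume fluxes) to rejections of the target solute; ``fit`` calibrates the
amplitude of the membrane's fixed-charge profile against an observed
rejection curve, which is how charge information is recovered from
filtration data when only rejection-vs-pressure measurements exist.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .physchem import SolutionState, WATER_VISCOSITY_25C
from .transport import Membrane, OperatingPoint, TransportSolution, solve_transport

__all__ = ["SEDETransportModel"]


class SEDETransportModel(BaseEstimator, RegressorMixin):
    """Forward SEDE rejection model with a calibratable charge amplitude.

    Parameters
    ----------
    membrane : Membrane
        Pore-scale membrane parameters (radius, thickness, dielectric
        constant, bipolar charge profile).
    feed : SolutionState
        Feed composition; must contain the target solute.
    solute : str
        Species whose rejection is reported (default "SDZ").
    driver : {'pressure', 'flux'}
        Whether ``predict``'s inputs are transmembrane pressures (Pa) or
        volume fluxes (m/s).
    charge_scale : float
        Multiplier applied to both charge plateaus before solving; ``fit``
        estimates it (``charge_scale_``) from data.
    rtol : ODE tolerance passed to the transport solver.

    The model can be used purely forward (``predict`` without ``fit``); in
    that case ``charge_scale`` is used as-is.
    """

    def __init__(
        self,
        membrane: Membrane = None,
        feed: SolutionState = None,
        solute: str = "SDZ",
        driver: str = "pressure",
        charge_scale: float = 1.0,
        mu: float = WATER_VISCOSITY_25C,
        rtol: float = 1e-8,
        shoot_rtol: float = 1e-7,
        fit_tol: float = 1e-7,
    ):
        self.membrane = membrane
        self.feed = feed
        self.solute = solute
        self.driver = driver
        self.charge_scale = charge_scale
        self.mu = mu
        self.rtol = rtol
        self.shoot_rtol = shoot_rtol
        self.fit_tol = fit_tol

    # -- internals -----------------------------------------------------
    def _membrane_scaled(self, scale: float) -> Membrane:
        prof = self.membrane.profile.scaled(scale)
        return replace(self.membrane, profile=prof)

    def _op(self, value: float) -> OperatingPoint:
        if self.driver == "pressure":
            return OperatingPoint(feed=self.feed, dP=float(value), mu=self.mu)
        if self.driver == "flux":
            return OperatingPoint(feed=self.feed, Jv=float(value), mu=self.mu)
        raise ValueError("driver must be 'pressure' or 'flux'")

    def _predict_with_scale(self, X, scale: float, guess_cache: dict | None = None) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        mem = self._membrane_scaled(scale)
        out = np.empty_like(x)
        order = np.argsort(x)
        guess = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in order:
                g = guess_cache.get(i, guess) if guess_cache is not None else guess
                sol = solve_transport(
                    mem, self._op(x[i]), rtol=self.rtol, permeate_guess=g,
                    profiles=False, shoot_rtol=self.shoot_rtol,
                    fixed_point_tol=self.fit_tol,
                )
                out[i] = sol.rejection[self.solute]
                if sol.converged:
                    guess = sol.permeate
                    if guess_cache is not None:
                        guess_cache[i] = sol.permeate
        return out

    # -- estimator API -------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Rejection of the target solute at each pressure (Pa) or flux (m/s)."""
        scale = getattr(self, "charge_scale_", self.charge_scale)
        return self._predict_with_scale(X, scale)

    def solve(self, value: float) -> TransportSolution:
        """Full intrapore solution at one operating point."""
        scale = getattr(self, "charge_scale_", self.charge_scale)
        return solve_transport(
            self._membrane_scaled(scale), self._op(value), rtol=self.rtol
        )

    def fit(self, X, y):
        """Calibrate the fixed-charge amplitude from observed rejections.

        Minimizes squared error in log-transmission, log(1−R), which keeps
        the objective sensitive when rejections approach 1. Sets
        ``charge_scale_``, ``membrane_`` and ``c_entrance_``.
        """
        if self.membrane is None or self.feed is None:
            raise ValueError("membrane and feed must be set before fitting")
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if X.shape != y.shape:
            raise ValueError("X and y must have the same length")
        log_t_obs = np.log(np.clip(1.0 - y, 1e-12, None))
        cache: dict = {}

        def objective(log_scale: float) -> float:
            r = self._predict_with_scale(X, np.exp(log_scale), guess_cache=cache)
            log_t = np.log(np.clip(1.0 - r, 1e-12, None))
            return float(np.sum((log_t - log_t_obs) ** 2))

        res = minimize_scalar(
            objective, bounds=(np.log(0.2), np.log(5.0)), method="bounded",
            options={"xatol": 5e-3},
        )
        self.charge_scale_ = float(np.exp(res.x))
        self.membrane_ = self._membrane_scaled(self.charge_scale_)
        self.c_entrance_ = self.membrane_.profile.c_entrance
        self.n_features_in_ = 1
        return self
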