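"""Shared fixtures: bundled membranes, feeds, and cached transport solves."""

from __future__ import annotations

import warnings

import pytest

from nanosede import fixtures as fx
from nanosede.transport import OperatingPoint, solve_transport

# the λ-cap warning fires for every oversized-solute solve; it is expected
# behaviour for the SDZ/tight-membrane combinations exercised everywhere here
warnings.filterwarnings("ignore", message="lambda=.*capped")


@pytest.fixture(scope="session")
def feed():
    return fx.default_feed()


@pytest.fixture(scope="session")
def membranes():
    return {name: fx.membrane(name) for name in fx.MEMBRANE_NAMES}


REFERENCE_FLUXES = (0.6e-4, 3e-4, 6e-4)


@pytest.fixture(scope="session")
def fixture_solutions(feed, membranes):
    """Converged solutions for all four membranes at the three reference fluxes.

    Computed once per session; shared by the field-mechanism, conservation
    and profile-pattern tests.
    """
    out = {}
    for name, mem in membranes.items():
        for jv in REFERENCE_FLUXES:
            sol = solve_transport(mem, OperatingPoint(feed=feed, Jv=jv))
            assert sol.converged, f"{name} at Jv={jv} did not converge"
            out[(name, jv)] = sol
    return out
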