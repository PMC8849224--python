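"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from xanpk import ConcentrationProfile, PKParameters

LN2 = np.log(2.0)


@pytest.fixture
def params():
    """A typical subject: fast absorption, caffeine/paraxanthine rates."""
    return PKParameters(ka=3.0, ke=0.16, km=0.089, fm=0.84, v_parent=30.0, v_metab=30.0)


def ode_oracle(t_grid, dose, params):
    """Numerical oracle for the gut -> parent -> metabolite cascade.

    Integrates the first-order ODE system

        dG/dt = -ka G,   dP/dt = ka G - ke P,   dM/dt = fm ke P - km M

    with G(0) = dose, and maps amounts to concentrations via the apparent
    volumes.  Independent of the closed forms under test.
    """
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(_, y):
        g, p, m = y
        return [
            -params.ka * g,
            params.ka * g - params.ke * p,
            params.fm * params.ke * p - params.km * m,
        ]

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid.max())),
        [dose, 0.0, 0.0],
        t_eval=t_grid,
        rtol=1e-10,
        atol=1e-12,
        method="LSODA",
    )
    assert sol.success
    return sol.y[1] / params.v_parent, sol.y[2] / params.v_metab


def profile_from_arrays(times, conc, analyte="caffeine", censored=None):
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if censored is None:
        censored = np.zeros_like(times, dtype=bool)
    return ConcentrationProfile(
        analyte=analyte, times=times, conc=conc, censored=np.asarray(censored, bool)
    )
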