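"""Independent oracles used by the test suite.

Each function here recomputes a quantity by a route deliberately
different from the library implementation it checks: dense grid
maximization instead of root finding, numerical quadrature instead of
closed forms, direct eigenvalue arithmetic instead of sampled
covariances.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from neqbind.binding import RestraintDefinition
from neqbind.constants import kt_kj


def bar_loglik(dg: float, wf: np.ndarray, wr_neg: np.ndarray, beta: float) -> float:
    """Fermi-function log-likelihood of bidirectional works (equal n).

    Stationary exactly at the Bennett self-consistent free energy when
    n_f = n_r.
    """
    xf = beta * (wf - dg)
    xr = -beta * (wr_neg - dg)
    return float(-np.logaddexp(0.0, xf).sum() - np.logaddexp(0.0, xr).sum())


def bar_grid_oracle(
    wf: np.ndarray,
    wr_neg: np.ndarray,
    beta: float,
    lo: float,
    hi: float,
    n_grid: int = 4001,
) -> float:
    """Maximize the Fermi log-likelihood on a dense grid, then polish
    with bounded scalar minimization around the best grid point."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([bar_loglik(g, wf, wr_neg, beta) for g in grid])
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda g: -bar_loglik(g, wf, wr_neg, beta),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def closed_form_trapezoid(f, grid: np.ndarray) -> float:
    """Explicit trapezoid sum written out independently of numpy."""
    total = 0.0
    for a, b in zip(grid, grid[1:]):
        total += 0.5 * (f(a) + f(b)) * (b - a)
    return total


def boresch_numeric(restr: RestraintDefinition, temperature: float) -> float:
    """6-D restrained configurational integral by product quadrature.

    The restraint energy is separable and the volume element factorizes
    (r^2 sin(tA) sin(tB)), so the 6-D integral is an exact product of
    1-D quadratures over the physical domains r in [0, inf),
    theta in [0, pi], phi in [-pi, pi].
    """
    kt = kt_kj(temperature)

    def gauss(k, x0):
        return lambda x: np.exp(-0.5 * k * (x - x0) ** 2 / kt)

    gr = gauss(restr.k_r, restr.r0)
    r_hi = restr.r0 + 15.0 * np.sqrt(kt / restr.k_r)
    i_r = quad(lambda x: x**2 * gr(x), 0.0, r_hi, limit=200)[0]
    i_ta = quad(
        lambda t: np.sin(t) * gauss(restr.k_theta_a, restr.theta_a0)(t),
        0.0,
        np.pi,
        limit=200,
    )[0]
    i_tb = quad(
        lambda t: np.sin(t) * gauss(restr.k_theta_b, restr.theta_b0)(t),
        0.0,
        np.pi,
        limit=200,
    )[0]
    i_phi = 1.0
    for k in (restr.k_phi_a, restr.k_phi_b, restr.k_phi_c):
        i_phi *= quad(gauss(k, 0.0), -np.pi, np.pi, limit=200)[0]
    z = i_r * i_ta * i_tb * i_phi
    return float(-kt * np.log(8.0 * np.pi**2 * restr.standard_volume / z))


def cgi_numeric_intersection(
    mf: float, vf: float, mr: float, vr: float
) -> float:
    """Numerical crossing point of two normal densities between their
    means (bisection on the log-density difference)."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    def diff(x):
        return norm.logpdf(x, mf, np.sqrt(vf)) - norm.logpdf(x, mr, np.sqrt(vr))

    lo, hi = min(mf, mr), max(mf, mr)
    return float(brentq(diff, lo, hi, xtol=1e-12))


def schlitter_closed_form_1d(
    mass_amu: float, variance_nm2: float, temperature: float
) -> float:
    """Single-coordinate Schlitter entropy, written out directly."""
    from neqbind.constants import AMU_KG, HBAR, KB_SI, NM_M, R_J_MOL_K

    arg = (
        KB_SI
        * temperature
        * np.e**2
        * (mass_amu * AMU_KG)
        * (variance_nm2 * NM_M**2)
        / HBAR**2
    )
    return 0.5 * R_J_MOL_K * np.log(1.0 + arg)
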