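"""Independent numerical oracles used by the tests.

These deliberately avoid the closed-form elliptic-function path of the
package: the beam oracle integrates the equilibrium ODE of the inextensible
rod by shooting, the chorda oracle bisects the scalar force balance, and the
elliptic-integral oracle uses adaptive quadrature of the defining integral.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq


def ode_elastica(theta_l: float, alpha: float, omega: float, n: int = 201):
    """Shooting solution of the cantilever rod under an inclined tip load.

    Dimensionless equilibrium: theta'' = -omega^2 cos(theta - alpha) with
    theta(0) = 0 (clamped root) and theta'(1) = 0 (free tip), the load of
    magnitude omega^2 pulling apically and backward, direction
    (-sin alpha, cos alpha).  Returns (s, x, y, theta, kappa0).
    """
    w2 = omega * omega

    def rhs(s, state):
        th, dth, x, y = state
        return [dth, -w2 * math.cos(th - alpha), math.cos(th), math.sin(th)]

    def tip_slope_rate(kappa0: float) -> float:
        sol = solve_ivp(rhs, [0.0, 1.0], [0.0, kappa0, 0.0, 0.0],
                        rtol=1e-11, atol=1e-13)
        return sol.y[1, -1]

    hi = max(4.0 * w2, 1.0)
    kappa0 = brentq(tip_slope_rate, 0.0, hi, xtol=1e-14)
    s = np.linspace(0.0, 1.0, n)
    sol = solve_ivp(rhs, [0.0, 1.0], [0.0, kappa0, 0.0, 0.0],
                    rtol=1e-11, atol=1e-13, t_eval=s)
    return s, sol.y[2], sol.y[3], sol.y[0], kappa0


def quadrature_incomplete_first(phi: float, k: float) -> float:
    """F[phi, k] by adaptive quadrature of its defining integral."""
    m = k * k
    val, _ = quad(lambda t: 1.0 / math.sqrt(1.0 - m * math.sin(t) ** 2), 0.0, phi,
                  epsabs=1e-13, epsrel=1e-13)
    return val


def bisection_stretch(P: float, c1: float, c2: float, A_ref: float,
                      lo: float = 1.0, hi: float = 8.0, tol: float = 1e-13) -> float:
    """Chorda equilibrium stretch by plain interval bisection."""
    def f(lam: float) -> float:
        eps = 0.5 * (lam * lam - 1.0)
        return c1 * math.expm1(c2 * eps) - lam * P / A_ref

    if P == 0:
        return 1.0
    while f(hi) < 0:
        hi *= 1.5
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if f(mid) < 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def linear_cantilever_tip_deflection(P: float, l: float, B: float) -> float:
    """Euler-Bernoulli small-deflection tip sag P l^3 / (3 B)."""
    return P * l ** 3 / (3.0 * B)
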