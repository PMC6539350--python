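"""Closed-form Euler elastica for a mitral leaflet under an inclined tip load.

Each leaflet is modelled as an inextensible cantilever of length ``l`` and
bending stiffness ``B``, clamped horizontally at the annular hinge and loaded
at its free edge by the tension of a chorda tendinea.  The load has magnitude
``P`` and acts along the chorda, inclined by ``alpha`` from the apical
(+y) axis, pointing apically and away from the valve midline (the tethering
direction).  The exact large-deflection solution is expressed through
incomplete elliptic integrals of the first and second kind and the Jacobi
amplitude.

Local frame: leaflet root at the origin, x along the annular plane toward the
opposite leaflet, y positive toward the apex.  Arclength is parametrised by
the dimensionless ``s`` in [0, 1].

Given the free-edge tangent angle ``theta_l`` (w.r.t. the annular plane) and
the load inclination ``alpha``, the solution is fully determined:

* elliptic eccentricity ``k``:          2 k^2 = 1 + sin(theta_l - alpha)
* reference amplitude ``phi_alpha``:    2 k^2 sin^2(phi_alpha) = 1 - sin(alpha)
* load frequency ``omega``:             omega = K[m] - F[phi_alpha, m], m = k^2
* load magnitude:                       P = B omega^2 / l^2

The amplitude runs from ``phi_alpha`` at the root to ``pi/2`` at the tip, so
the tip curvature vanishes identically (pure end-point load) and the tangent
angle field is ``theta(s) = alpha + atan2(2 k^2 sin^2 phi - 1,
2 k sin(phi) dn(phi))`` with curvature ``kappa(s) = 2 k omega cos(phi(s))/l``.

All elliptic routines follow the SciPy parameter convention ``m = k^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipe, ellipeinc, ellipj, ellipk, ellipkinc

__all__ = [
    "ElasticaParams",
    "ElasticaSolution",
    "eccentricity_from_angles",
    "reference_amplitude",
    "load_frequency",
    "tip_load",
    "amplitude_at",
    "shape",
    "tip_position",
    "curvature_at",
    "root_moment",
    "solve_elastica",
]

#: below this dimensionless load frequency the beam is treated as straight
#: (the parametric shape is 0/0 at omega = 0; the limit is the undeformed rod;
#: round-off in phi_alpha near pi/2 leaves omega ~ 1e-8 for a truly unloaded
#: beam, so the threshold sits well above that and still corresponds to a
#: negligible load P ~ B*1e-12/l^2)
OMEGA_STRAIGHT_TOL = 1e-6


class ElasticaDomainError(ValueError):
    """Raised when (theta_l, alpha) do not define a valid tensioned elastica."""


@dataclass(frozen=True)
class ElasticaParams:
    """Geometric and material inputs of one leaflet.

    Parameters
    ----------
    l : float
        Leaflet length [mm], > 0.
    B : float
        Bending stiffness [mN mm^2], > 0.
    theta_l : float
        Free-edge tangent angle w.r.t. the annular (horizontal) axis [rad],
        in (-pi/2, pi/2).
    alpha : float
        Load (chorda) inclination w.r.t. the apical y-axis [rad], in [0, pi/2).
    """

    l: float
    B: float
    theta_l: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.l > 0 and self.B > 0):
            raise ValueError(f"l and B must be positive (got l={self.l}, B={self.B})")
        if not (-math.pi / 2 < self.theta_l < math.pi / 2):
            raise ValueError(f"theta_l={self.theta_l!r} outside (-pi/2, pi/2)")
        if not (0 <= self.alpha < math.pi / 2):
            raise ValueError(f"alpha={self.alpha!r} outside [0, pi/2)")


@dataclass(frozen=True)
class ElasticaSolution:
    """Fully solved deformed state of one leaflet.

    ``tip`` is the free-edge position b = (x_l, y_l) in mm (local frame) and
    ``root_moment`` the bending moment magnitude B*kappa(0) at the clamped
    root in mN mm.  ``P = B omega^2 / l^2`` by construction.
    """

    params: ElasticaParams
    k: float
    phi_alpha: float
    omega: float
    P: float
    tip: np.ndarray = field(repr=False)
    root_moment: float


def eccentricity_from_angles(theta_l: float, alpha: float) -> float:
    """Elliptic eccentricity k from 2 k^2 = 1 + sin(theta_l - alpha)."""
    k2 = 0.5 * (1.0 + math.sin(theta_l - alpha))
    if not (0.0 < k2 <= 1.0):
        raise ElasticaDomainError(
            f"degenerate load/slope pairing: k^2={k2} for theta_l={theta_l}, alpha={alpha}"
        )
    return math.sqrt(k2)


def reference_amplitude(k: float, alpha: float) -> float:
    """Root amplitude phi_alpha from 2 k^2 sin^2(phi_alpha) = 1 - sin(alpha)."""
    arg = (1.0 - math.sin(alpha)) / (2.0 * k * k)
    if arg > 1.0 + 1e-12:
        raise ElasticaDomainError(
            f"incompatible (k, alpha): sin^2(phi_alpha)={arg} > 1"
        )
    return math.asin(math.sqrt(min(arg, 1.0)))


def load_frequency(k: float, phi_alpha: float) -> float:
    """Dimensionless load frequency omega = K[m] - F[phi_alpha, m], m = k^2."""
    m = k * k
    omega = ellipk(m) - ellipkinc(phi_alpha, m)
    # round-off can leave a tiny negative residue when phi_alpha ~ pi/2
    return max(float(omega), 0.0)


def tip_load(omega: float, l: float, B: float) -> float:
    """End-point load magnitude P = B omega^2 / l^2 [mN]."""
    return B * omega * omega / (l * l)


def amplitude_at(s, omega: float, phi_alpha: float, k: float):
    """Jacobi amplitude phi(s) = am[omega s + F[phi_alpha, k], k].

    ``phi(0) = phi_alpha`` and ``phi(1) = pi/2`` (zero tip curvature); phi is
    monotone non-decreasing for omega > 0.  Accepts scalar or array ``s``.
    """
    m = k * k
    u = omega * np.asarray(s, dtype=float) + ellipkinc(phi_alpha, m)
    _, _, _, phi = ellipj(u, m)
    return phi


def _shape_hat(s, k: float, phi_alpha: float, omega: float, alpha: float):
    """Deformed shape (x/l, y/l) at dimensionless arclength s."""
    s = np.asarray(s, dtype=float)
    if omega < OMEGA_STRAIGHT_TOL:
        # zero-load limit: straight horizontal rod
        return s.copy(), np.zeros_like(s)
    m = k * k
    F_alpha = ellipkinc(phi_alpha, m)
    u = omega * s + F_alpha
    _, cn, _, phi = ellipj(u, m)
    # F[phi] - F[phi_alpha] telescopes to omega*s along the solution
    G = omega * s - 2.0 * (ellipeinc(phi, m) - ellipeinc(phi_alpha, m))
    dcos = np.cos(phi_alpha) - cn  # cos(phi_alpha) - cos(phi(s))
    ca, sa = math.cos(alpha), math.sin(alpha)
    x = (2.0 * k * ca / omega) * dcos - (sa / omega) * G
    y = (ca / omega) * G + (2.0 * k * sa / omega) * dcos
    return x, y


def shape(s, solution: ElasticaSolution):
    """Deformed centreline point(s) (x, y) in mm at arclength fraction s."""
    p = solution.params
    x, y = _shape_hat(s, solution.k, solution.phi_alpha, solution.omega, p.alpha)
    return p.l * x, p.l * y


def tip_position(solution: ElasticaSolution) -> np.ndarray:
    """Free-edge position b = (x_l, y_l) [mm]: the shape evaluated at s = 1."""
    x, y = shape(1.0, solution)
    return np.array([float(x), float(y)])


def curvature_at(s, solution: ElasticaSolution):
    """Signed curvature kappa(s) = 2 k omega cos(phi(s)) / l [1/mm]."""
    phi = amplitude_at(s, solution.omega, solution.phi_alpha, solution.k)
    return 2.0 * solution.k * solution.omega * np.cos(phi) / solution.params.l


def tangent_angle_at(s, solution: ElasticaSolution):
    """Tangent angle theta(s) [rad] of the deformed centreline."""
    k, alpha = solution.k, solution.params.alpha
    phi = amplitude_at(s, solution.omega, solution.phi_alpha, solution.k)
    m = k * k
    sn = np.sin(phi)
    dn = np.sqrt(1.0 - m * sn * sn)
    return alpha + np.arctan2(2.0 * m * sn * sn - 1.0, 2.0 * k * sn * dn)


def root_moment(solution: ElasticaSolution) -> float:
    """Bending moment magnitude at the clamped root, M = B |kappa(0)| [mN mm]."""
    kappa0 = 2.0 * solution.k * solution.omega * math.cos(solution.phi_alpha)
    return solution.params.B * abs(kappa0) / solution.params.l


def solve_elastica(theta_l: float, alpha: float, l: float, B: float) -> ElasticaSolution:
    """Solve the full elastica for given end-slope and load inclination.

    Composes eccentricity, reference amplitude, load frequency, load, tip
    position and root moment into one consistent state.  The degenerate
    zero-load case (omega -> 0, i.e. theta_l -> 0) returns the straight
    horizontal configuration analytically.
    """
    params = ElasticaParams(l=l, B=B, theta_l=theta_l, alpha=alpha)
    k = eccentricity_from_angles(theta_l, alpha)
    phi_alpha = reference_amplitude(k, alpha)
    omega = load_frequency(k, phi_alpha)
    P = tip_load(omega, l, B)
    x, y = _shape_hat(1.0, k, phi_alpha, omega, alpha)
    tip = np.array([l * float(x), l * float(y)])
    sol = ElasticaSolution(
        params=params, k=k, phi_alpha=phi_alpha, omega=omega, P=P, tip=tip,
        root_moment=B * abs(2.0 * k * omega * math.cos(phi_alpha)) / l,
    )
    return sol


# ---------------------------------------------------------------------------
# fast kernel used by the configuration solvers (no dataclass overhead)

def _tip_state(theta_l: float, alpha: float):
    """(x_hat, y_hat, omega, k, phi_alpha) of the unit-length elastica tip."""
    k = eccentricity_from_angles(theta_l, alpha)
    phi_alpha = reference_amplitude(k, alpha)
    omega = load_frequency(k, phi_alpha)
    if omega < OMEGA_STRAIGHT_TOL:
        return 1.0, 0.0, omega, k, phi_alpha
    m = k * k
    # at the tip phi = pi/2: cn = 0, E(pi/2) = E(m) complete
    G = omega - 2.0 * (ellipe(m) - ellipeinc(phi_alpha, m))
    dcos = math.cos(phi_alpha)
    ca, sa = math.cos(alpha), math.sin(alpha)
    x = (2.0 * k * ca / omega) * dcos - (sa / omega) * G
    y = (ca / omega) * G + (2.0 * k * sa / omega) * dcos
    return x, y, omega, k, phi_alpha
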