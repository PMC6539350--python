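"""Identification of the preoperative ischemic-regurgitation configuration.

The clinical inputs (annular diameter, tenting height TH, end-diastolic
interpapillary distance IPD, leaflet angles delta) do not determine the
structural state directly; the chorda inclinations are hidden.  They are
recovered by a random iterative search: chorda angles (alpha_a, alpha_p) are
drawn, each leaflet end-slope theta_l is solved so that the elastica tip
falls on the leaflet-angle ray

    y_l = x_l tan(delta),

and a draw is accepted once both tip depths fall in the tenting-height
window and the papillary distance in the IPD window:

    TH - dTH <= y_l^i <= TH + dTH,    IPD - dIPD <= d <= IPD + dIPD.

An accepted (or, in best-compatibility mode, the least-incompatible)
configuration is then finalised: the elastica gives the preoperative loads
P_pre, node equilibrium gives the chorda stretches lam_pre, and the pull-back
L_c = |b - m| / lam_pre fixes the chordae reference lengths used by every
postoperative prediction.

Note that the tip-depth window may be geometrically unreachable: on the
delta-ray the tip depth is chord*sin(delta) <= l*sin(delta).  When the
requested TH exceeds that bound no draw can be accepted; ``mode="best"``
then returns the closest achievable configuration instead of raising, which
is also the documented path for reproducing the reference case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import elastica as el
from .chordae import ChordaState, equilibrium_stretch, reference_length
from .valve_system import (
    SystemConfiguration,
    ValveMeasurements,
    interpapillary_distance,
    pm_position_anterior,
    pm_position_posterior,
)

__all__ = [
    "CompatibilityWindows",
    "PreopConfiguration",
    "PreopIdentificationError",
    "leaflet_angle_solve",
    "identify_preop",
    "finalize_preop",
]

#: chorda-angle sampling range [rad]; anatomically plausible inclinations
ALPHA_RANGE = (math.radians(1.0), math.radians(60.0))

_THETA_GRID = np.linspace(1e-4, math.pi / 2 * 0.999, 160)


class PreopIdentificationError(RuntimeError):
    """No draw satisfied the compatibility windows within max_iter."""


@dataclass(frozen=True)
class CompatibilityWindows:
    """Half-widths of the acceptance windows [mm].

    Defaults are the reported measurement spreads of the reference cohort.
    """

    dTH: float = 0.13
    dIPD: float = 0.39

    def __post_init__(self) -> None:
        if self.dTH <= 0 or self.dIPD <= 0:
            raise ValueError("window half-widths must be positive")


@dataclass(frozen=True)
class PreopConfiguration:
    """Finalised preoperative state: geometry plus loads/stretches/moments."""

    system: SystemConfiguration
    P_pre_a: float
    P_pre_p: float
    lam_pre_a: float
    lam_pre_p: float
    L_c_a: float
    L_c_p: float
    M_pre_a: float
    M_pre_p: float
    T_pre_a: float
    T_pre_p: float
    rng_seed: int | None
    n_iterations: int
    window_miss: float      # 0 when all windows are satisfied


def leaflet_angle_solve(delta: float, alpha: float, l: float, B: float) -> float:
    """End-slope theta_l placing the elastica tip on the ray y = x tan(delta).

    Scalar root of f(theta) = y_hat - x_hat tan(delta) over theta in
    (0, pi/2); the deflection grows monotonically with theta, giving a single
    sign change which is polished with Brent's method.
    """
    if not (0.0 < delta < math.pi / 2):
        raise ValueError(f"delta must lie in (0, pi/2), got {delta}")
    t = math.tan(delta)

    def f(theta: float) -> float:
        x, y, *_ = el._tip_state(theta, alpha)
        return y - x * t

    vals = [f(th) for th in _THETA_GRID]
    for i in range(len(_THETA_GRID) - 1):
        if vals[i] == 0.0:
            return float(_THETA_GRID[i])
        if vals[i] * vals[i + 1] < 0:
            return brentq(f, _THETA_GRID[i], _THETA_GRID[i + 1], xtol=1e-13)
    raise ValueError(
        f"no end-slope satisfies the leaflet angle {math.degrees(delta):.1f} deg "
        f"for alpha={math.degrees(alpha):.1f} deg over theta in "
        f"({_THETA_GRID[0]:.2g}, {_THETA_GRID[-1]:.4g}) rad"
    )


def _build_geometry(meas: ValveMeasurements, alpha_a: float, alpha_p: float
                    ) -> SystemConfiguration:
    """Assemble the geometric configuration for a chorda-angle draw."""
    theta_a = leaflet_angle_solve(meas.delta_a, alpha_a, meas.l_a, meas.B)
    theta_p = leaflet_angle_solve(meas.delta_p, alpha_p, meas.l_p, meas.B)
    sol_a = el.solve_elastica(theta_a, alpha_a, meas.l_a, meas.B)
    sol_p = el.solve_elastica(theta_p, alpha_p, meas.l_p, meas.B)
    b_a = sol_a.tip                                     # local == global
    tip_p_local = sol_p.tip
    b_p = np.array([meas.MAD_pre - tip_p_local[0], tip_p_local[1]])
    m_a = pm_position_anterior(b_a, alpha_a, meas.h_a)
    m_p = pm_position_posterior(tip_p_local, alpha_p, meas.h_p, meas.MAD_pre)
    return SystemConfiguration(
        a_a=np.zeros(2), a_p=np.array([meas.MAD_pre, 0.0]),
        b_a=b_a, b_p=b_p, m_a=m_a, m_p=m_p,
        theta_a=theta_a, theta_p=theta_p, alpha_a=alpha_a, alpha_p=alpha_p,
        elastica_a=sol_a, elastica_p=sol_p,
    )


def _window_miss(config: SystemConfiguration, meas: ValveMeasurements,
                 win: CompatibilityWindows) -> float:
    """Normalised distance to the compatibility windows (0 inside)."""
    d = config.interpapillary_distance
    miss = max(0.0, abs(config.b_a[1] - meas.TH_pre) - win.dTH) / meas.TH_pre
    miss += max(0.0, abs(config.b_p[1] - meas.TH_pre) - win.dTH) / meas.TH_pre
    miss += max(0.0, abs(d - meas.IPD_pre) - win.dIPD) / meas.IPD_pre
    return miss


def identify_preop(meas: ValveMeasurements,
                   win: CompatibilityWindows | None = None,
                   seed: int | None = 0,
                   max_iter: int = 10_000,
                   mode: str = "accept_first",
                   symmetric: bool = False) -> PreopConfiguration:
    """Random iterative identification of the preoperative configuration.

    Parameters
    ----------
    mode : {"accept_first", "best"}
        ``accept_first`` returns the first draw inside all windows and raises
        :class:`PreopIdentificationError` after ``max_iter`` misses.  ``best``
        always runs ``max_iter`` draws and returns the draw of minimum window
        distance — inside the windows when they are reachable, the closest
        achievable configuration when they are not.
    symmetric : bool
        Draw a single chorda angle for both sides (symmetric tethering, the
        reference study condition).  The asymmetric identification is
        underdetermined: one interpapillary distance constrains two angles.

    Deterministic for a given seed.
    """
    if mode not in ("accept_first", "best"):
        raise ValueError(f"unknown mode {mode!r}")
    win = win or CompatibilityWindows()
    rng = np.random.default_rng(seed)
    best: SystemConfiguration | None = None
    best_miss = math.inf
    n_done = 0
    for i in range(max_iter):
        alpha_a = rng.uniform(*ALPHA_RANGE)
        alpha_p = alpha_a if symmetric else rng.uniform(*ALPHA_RANGE)
        n_done = i + 1
        try:
            config = _build_geometry(meas, alpha_a, alpha_p)
        except (ValueError, el.ElasticaDomainError):
            continue
        miss = _window_miss(config, meas, win)
        if miss < best_miss:
            best_miss, best = miss, config
        if miss == 0.0 and mode == "accept_first":
            break
    else:
        if mode == "accept_first":
            detail = "no draw produced a valid geometry"
            if best is not None:
                d = best.interpapillary_distance
                detail = (
                    f"closest miss {best_miss:.4f} at tip depths "
                    f"({best.b_a[1]:.2f}, {best.b_p[1]:.2f}) mm vs TH window "
                    f"{meas.TH_pre}+-{win.dTH}, IPD {d:.2f} vs "
                    f"{meas.IPD_pre}+-{win.dIPD}"
                )
            raise PreopIdentificationError(
                f"compatibility windows not met in {max_iter} draws: {detail}"
            )
    if best is None:
        raise PreopIdentificationError(
            f"no valid geometry found in {max_iter} draws"
        )
    return finalize_preop(best, meas, rng_seed=seed, n_iterations=n_done,
                          window_miss=best_miss)


def finalize_preop(config: SystemConfiguration, meas: ValveMeasurements,
                   rng_seed: int | None = None, n_iterations: int = 0,
                   window_miss: float = 0.0) -> PreopConfiguration:
    """Attach loads, stretches and reference chorda lengths to a geometry.

    The elastica load P_pre follows from the solved (theta, alpha); node
    equilibrium yields lam_pre; the pull-back |b - m| / lam_pre fixes L_c.
    """
    mat = meas.material
    P_a = config.elastica_a.P
    P_p = config.elastica_p.P
    lam_a = equilibrium_stretch(P_a, mat)
    lam_p = equilibrium_stretch(P_p, mat)
    l_c_a = float(np.linalg.norm(config.b_a - config.m_a))
    l_c_p = float(np.linalg.norm(config.b_p - config.m_p))
    L_c_a = reference_length(l_c_a, lam_a)
    L_c_p = reference_length(l_c_p, lam_p)
    system = SystemConfiguration(
        **{f: getattr(config, f) for f in (
            "a_a", "a_p", "b_a", "b_p", "m_a", "m_p",
            "theta_a", "theta_p", "alpha_a", "alpha_p",
            "elastica_a", "elastica_p")},
        chorda_a=ChordaState.from_lengths(L_c_a, l_c_a, mat),
        chorda_p=ChordaState.from_lengths(L_c_p, l_c_p, mat),
    )
    return PreopConfiguration(
        system=system,
        P_pre_a=P_a, P_pre_p=P_p,
        lam_pre_a=lam_a, lam_pre_p=lam_p,
        L_c_a=L_c_a, L_c_p=L_c_p,
        M_pre_a=config.elastica_a.root_moment,
        M_pre_p=config.elastica_p.root_moment,
        T_pre_a=P_a / mat.A_ref, T_pre_p=P_p / mat.A_ref,
        rng_seed=rng_seed, n_iterations=n_iterations, window_miss=window_miss,
    )
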