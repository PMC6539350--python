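"""Postoperative prediction: restrictive annuloplasty and papillary approximation.

Three surgical scenarios are solved from one identified preoperative state:

``OPTIMIZED_PMA``
    Annular restriction r (applied to the posterior hinge) combined with free
    papillary-muscle displacements u^a = (u_x^a, zeta_a u_x^a),
    u^p = (-u_x^p, zeta_p u_x^p).  For a fixed orientation pair
    (zeta_a, zeta_p) the seven unknowns (theta_a, theta_p, alpha_a, alpha_p,
    u_x^a, u_x^p, r) satisfy seven equations: node equilibrium and chorda
    congruency per side, tip coaptation y_l^i = TH_opt, and the annular width
    x_l^a + x_l^p = MAD_pre - r.  The orientations are design variables,
    optimised by random search to minimise the chordae stress.

``RA_ONLY``
    Annuloplasty without approximation: the papillary muscles are motionless
    and the restriction decouples into per-side hinge shifts r = r_a + r_p.
    Coaptation at the surgical target height is generally *unreachable* with
    the muscles pinned wide — the chorda stress exceeds what the leaflet can
    transmit at that height — so the two free edges are instead required to
    meet at a common point whose depth is free.  Equilibrium and congruency
    per side plus the two meeting conditions determine (theta_a, theta_p,
    alpha_a, alpha_p); the residual tenting above TH_opt and the required
    restriction are outcomes, expressing the recurrence risk of annuloplasty
    alone under severe tethering.

``COMPLETE_PMA``
    Approximation to a prescribed interpapillary distance (default 10 mm).
    Both muscles share one displacement orientation zeta, which becomes the
    unknown balancing the added IPD equation.  The taut chordae bound how
    close the muscles can come (each papillary head keeps its equilibrium
    distance lam*L_c from the coapted tip); a prescription below that bound
    is reported as unreachable or, on request, replaced by the nearest
    achievable distance.

Solver structure: at a prescribed tip depth the coaptation constraint pins
the leaflet end-slope given the chorda inclination, node equilibrium pins
the chorda stretch given the leaflet load, and congruency then places the
papillary head — so every scenario collapses to scalar root-finding in the
chorda inclinations.  Solutions are verified against the full residual
vector of the coupled system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from . import elastica as el
from .chordae import ChordaState, cauchy_stress, equilibrium_stretch, green_strain
from .preop import PreopConfiguration
from .valve_system import SystemConfiguration, ValveMeasurements, interpapillary_distance

__all__ = [
    "Scenario",
    "SurgicalVariables",
    "PostopConfiguration",
    "IndicatorSet",
    "PostopSolveError",
    "postop_residuals",
    "solve_scenario",
    "optimize_pma",
    "indicators",
    "compare_scenarios",
]

#: orientation-coefficient sampling range for the random zeta search
ZETA_RANGE = (-2.0, 2.0)
#: draws of the random orientation search
N_DRAWS_DEFAULT = 200
#: relative band around the best objective within which the draw of smallest
#: total papillary displacement is preferred (the stress landscape over the
#: orientations is nearly flat; parsimony of the displacement disambiguates)
TIE_TOLERANCE = 0.02

_ALPHA_GRID = np.radians(np.linspace(0.2, 80.0, 81))
_THETA_GRID = np.linspace(1e-3, math.pi / 2 * 0.999, 120)


class Scenario(Enum):
    OPTIMIZED_PMA = "optimized"
    RA_ONLY = "ra-only"
    COMPLETE_PMA = "complete-pma"


class PostopSolveError(RuntimeError):
    """The scenario system could not be solved."""


@dataclass(frozen=True)
class SurgicalVariables:
    """Annular restriction and papillary displacement of one solution."""

    r: float                       # total annular restriction [mm]
    u_a: np.ndarray                # anterior PM displacement [mm]
    u_p: np.ndarray                # posterior PM displacement [mm]
    zeta_a: float | None = None    # orientation coefficients (None: not used)
    zeta_p: float | None = None
    r_a: float | None = None       # per-side split (RA_ONLY)
    r_p: float | None = None


@dataclass(frozen=True)
class IndicatorSet:
    """Non-dimensional post/pre effectiveness ratios (root moments, chorda
    nominal stresses, chorda stretches)."""

    Mr_a: float
    Mr_p: float
    Tr_a: float
    Tr_p: float
    lr_a: float
    lr_p: float


@dataclass(frozen=True)
class PostopConfiguration:
    system: SystemConfiguration
    surgical: SurgicalVariables
    scenario: Scenario
    P_po_a: float
    P_po_p: float
    lam_po_a: float
    lam_po_p: float
    M_po_a: float
    M_po_p: float
    T_po_a: float
    T_po_p: float
    MAD_po: float
    IPD_po: float
    residual_norm: float
    provenance: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# scalar building blocks

def _theta_for_tip_depth(l: float, alpha: float, y_target: float,
                         hint: float | None = None) -> float | None:
    """End-slope putting the tip at depth y_target; None if unreachable.

    The tip depth grows monotonically with the end-slope over the admissible
    range, so the root is bracketed by a scan (or, much faster, by expanding
    a window around a ``hint`` from a neighbouring inclination).
    """

    def f(theta: float) -> float:
        return el._tip_state(theta, alpha)[1] * l - y_target

    if hint is not None and np.isfinite(hint):
        lo = max(float(_THETA_GRID[0]), hint - 0.05)
        hi = min(float(_THETA_GRID[-1]), hint + 0.05)
        flo, fhi = f(lo), f(hi)
        for _ in range(8):
            if flo * fhi <= 0:
                return brentq(f, lo, hi, xtol=1e-13)
            lo = max(float(_THETA_GRID[0]), lo - 0.1)
            hi = min(float(_THETA_GRID[-1]), hi + 0.1)
            flo, fhi = f(lo), f(hi)
        # hint failed; fall through to the full scan
    vals = [f(t) for t in _THETA_GRID]
    for i in range(len(_THETA_GRID) - 1):
        if vals[i] == 0.0:
            return float(_THETA_GRID[i])
        if vals[i] * vals[i + 1] < 0:
            return brentq(f, _THETA_GRID[i], _THETA_GRID[i + 1], xtol=1e-13)
    return None


def _scan_roots(f, grid) -> list[float]:
    """All sign-change roots of f over a grid (NaN-tolerant)."""
    roots = []
    prev_x, prev_v = None, None
    for x in grid:
        v = f(x)
        if v is None or not np.isfinite(v):
            prev_x, prev_v = None, None
            continue
        if prev_v is not None and (v == 0.0 or prev_v * v < 0):
            roots.append(brentq(f, prev_x, x, xtol=1e-14))
        prev_x, prev_v = x, v
    return roots


class _Workspace:
    """Per-(preop, measurements) solver cache.

    Stores coarse theta(alpha) tables per leaflet so that repeated side-state
    evaluations (hundreds per orientation draw) reuse bracket hints instead
    of re-scanning the full end-slope range.
    """

    def __init__(self, preop: PreopConfiguration, meas: ValveMeasurements):
        self.preop = preop
        self.meas = meas
        self._theta_tables: dict[tuple[str, float], np.ndarray] = {}
        self._branch_tables: dict[tuple[str, float], list] = {}

    def _table(self, side: str, y_target: float) -> np.ndarray:
        key = (side, round(y_target, 9))
        tab = self._theta_tables.get(key)
        if tab is None:
            l = self.meas.l_a if side == "a" else self.meas.l_p
            tab = np.full(len(_ALPHA_GRID), np.nan)
            hint = None
            for i, a in enumerate(_ALPHA_GRID):
                th = _theta_for_tip_depth(l, float(a), y_target, hint=hint)
                if th is not None:
                    tab[i] = th
                    hint = th
            self._theta_tables[key] = tab
        return tab

    def theta_of(self, side: str, alpha: float, y_target: float) -> float | None:
        l = self.meas.l_a if side == "a" else self.meas.l_p
        tab = self._table(side, y_target)
        i = int(np.clip(np.searchsorted(_ALPHA_GRID, alpha), 1, len(tab) - 1))
        hint = tab[i - 1] if np.isfinite(tab[i - 1]) else tab[i]
        return _theta_for_tip_depth(l, alpha, y_target,
                                    hint=float(hint) if np.isfinite(hint) else None)

    def side_state(self, alpha: float, side: str, tip_x: float | None = None,
                   tip_depth: float | None = None):
        """Mechanical state of one side at a postop chorda inclination.

        The tip depth (default TH_opt) pins the end-slope, the elastica load
        pins the equilibrium stretch, and congruency places the papillary
        head.  For the posterior side ``tip_x`` (the shared coaptation
        abscissa) must be given.  None when the geometry is unreachable.
        """
        meas = self.meas
        y = meas.TH_opt if tip_depth is None else tip_depth
        l = meas.l_a if side == "a" else meas.l_p
        L_c = self.preop.L_c_a if side == "a" else self.preop.L_c_p
        theta = self.theta_of(side, alpha, y)
        if theta is None:
            return None
        x_hat, _, omega, k, phi_alpha = el._tip_state(theta, alpha)
        P = meas.B * omega ** 2 / l ** 2
        lam = equilibrium_stretch(P, meas.material)
        l_c = lam * L_c
        if side == "a":
            tip = np.array([x_hat * l, y])
            m = tip + l_c * np.array([-math.sin(alpha), math.cos(alpha)])
        else:
            tip = np.array([tip_x, y])
            m = tip + l_c * np.array([math.sin(alpha), math.cos(alpha)])
        M = meas.B * abs(2.0 * k * omega * math.cos(phi_alpha)) / l
        return {
            "theta": theta, "alpha": alpha, "tip": tip, "m": m, "P": P,
            "lam": lam, "M": M, "x_loc": x_hat * l, "l_c": l_c,
        }

    def tethered_state(self, alpha: float, side: str, shift: float = 0.0,
                       hint: float | None = None):
        """Equilibrium state of one side with its papillary muscle prescribed.

        Used by RA_ONLY: the muscle sits ``shift`` mm basally (toward the
        annulus) of its preoperative position.  For a chorda inclination
        alpha the tip depth is an unknown — congruency places the tip on the
        chorda ray through the papillary head and the end-slope solves the
        node equilibrium (the residual decreases monotonically with the
        end-slope, so the root is unique).  None when no tethered
        equilibrium exists.
        """
        meas = self.meas
        mat = meas.material
        m0 = self.preop.system.m_a if side == "a" else self.preop.system.m_p
        m = m0 - np.array([0.0, shift])
        L_c = self.preop.L_c_a if side == "a" else self.preop.L_c_p
        l = meas.l_a if side == "a" else meas.l_p

        def res(theta: float) -> float:
            x_hat, y_hat, omega, *_ = el._tip_state(theta, alpha)
            y = y_hat * l
            dy = m[1] - y
            if dy <= 0:
                return np.nan
            lam = dy / math.cos(alpha) / L_c
            sigma = cauchy_stress(green_strain(lam), mat) if lam >= 1.0 else 0.0
            P = meas.B * omega ** 2 / l ** 2
            return (sigma - lam * P / mat.A_ref) / mat.c1

        theta = None
        if hint is not None and np.isfinite(hint):
            lo = max(float(_THETA_GRID[0]), hint - 0.05)
            hi = min(float(_THETA_GRID[-1]), hint + 0.05)
            flo, fhi = res(lo), res(hi)
            for _ in range(8):
                if np.isfinite(flo) and np.isfinite(fhi) and flo * fhi <= 0:
                    theta = brentq(res, lo, hi, xtol=1e-13)
                    break
                lo = max(float(_THETA_GRID[0]), lo - 0.1)
                hi = min(float(_THETA_GRID[-1]), hi + 0.1)
                flo, fhi = res(lo), res(hi)
        if theta is None:
            roots = _scan_roots(res, _THETA_GRID)
            if not roots:
                return None
            theta = roots[0]
        x_hat, y_hat, omega, k, phi_alpha = el._tip_state(theta, alpha)
        y = y_hat * l
        dy = m[1] - y
        lam = dy / math.cos(alpha) / L_c
        if lam < 1.0:
            return None
        bx = m[0] + dy * math.tan(alpha) if side == "a" else m[0] - dy * math.tan(alpha)
        tip = np.array([bx, y])
        P = meas.B * omega ** 2 / l ** 2
        M = meas.B * abs(2.0 * k * omega * math.cos(phi_alpha)) / l
        return {"theta": theta, "alpha": alpha, "tip": tip, "m": m,
                "P": P, "lam": lam, "M": M, "x_loc": x_hat * l,
                "l_c": lam * L_c}

    def tethered_branch(self, side: str, shift: float):
        """Tethered states tabulated over the inclination grid (with NaNs)."""
        key = (side, round(shift, 9))
        tab = self._branch_tables.get(key)
        if tab is None:
            states, hint = [], None
            for a in _ALPHA_GRID:
                st = self.tethered_state(float(a), side, shift=shift, hint=hint)
                states.append(st)
                hint = st["theta"] if st is not None else None
            tab = states
            self._branch_tables[key] = tab
        return tab


# ---------------------------------------------------------------------------
# full residual vector (validation / diagnostics)

def postop_residuals(unknowns, preop: PreopConfiguration, meas: ValveMeasurements,
                     zeta_a: float, zeta_p: float) -> np.ndarray:
    """Scaled residual vector of the seven-equation coupled system.

    ``unknowns = (theta_a, theta_p, alpha_a, alpha_p, u_x_a, u_x_p, r)``.
    Components: two node equilibria (scaled by c1), two congruencies [rad],
    two coaptation heights and one annular-width constraint (scaled by
    MAD_pre).  Geometrically infeasible points yield large finite residuals
    rather than exceptions so that solvers can traverse them.
    """
    theta_a, theta_p, alpha_a, alpha_p, u_x_a, u_x_p, r = unknowns
    mat = meas.material
    try:
        xa, ya, om_a, *_ = el._tip_state(theta_a, alpha_a)
        xp, yp, om_p, *_ = el._tip_state(theta_p, alpha_p)
    except (ValueError, el.ElasticaDomainError):
        return np.full(7, 1e3)
    b_a = np.array([xa * meas.l_a, ya * meas.l_a])
    b_p = np.array([meas.MAD_pre - r - xp * meas.l_p, yp * meas.l_p])
    m_a = preop.system.m_a + np.array([u_x_a, zeta_a * u_x_a])
    m_p = preop.system.m_p + np.array([-u_x_p, zeta_p * u_x_p])
    P_a = meas.B * om_a ** 2 / meas.l_a ** 2
    P_p = meas.B * om_p ** 2 / meas.l_p ** 2
    ch_a = ChordaState.from_lengths(preop.L_c_a, float(np.linalg.norm(b_a - m_a)), mat)
    ch_p = ChordaState.from_lengths(preop.L_c_p, float(np.linalg.norm(b_p - m_p)), mat)
    va, vp = m_a - b_a, m_p - b_p
    return np.array([
        (ch_a.sigma - ch_a.lam * P_a / mat.A_ref) / mat.c1,
        (ch_p.sigma - ch_p.lam * P_p / mat.A_ref) / mat.c1,
        (math.pi / 2 + alpha_a) - math.atan2(va[1], va[0]),
        (math.pi / 2 - alpha_p) - math.atan2(vp[1], vp[0]),
        (b_a[1] - meas.TH_opt) / meas.MAD_pre,
        (b_p[1] - meas.TH_opt) / meas.MAD_pre,
        (xa * meas.l_a + xp * meas.l_p - (meas.MAD_pre - r)) / meas.MAD_pre,
    ])


# ---------------------------------------------------------------------------
# scenario solves

def _solve_fixed_zeta(ws: _Workspace, zeta_a: float, zeta_p: float) -> list[dict]:
    """All solutions of the coupled system at fixed orientations.

    The anterior side decouples: its displacement-orientation match
    g_a(alpha) = du_y - zeta_a du_x has isolated roots; the posterior side is
    solved conditionally on the anterior coaptation abscissa.
    """
    preop, meas = ws.preop, ws.meas
    m_pre_a, m_pre_p = preop.system.m_a, preop.system.m_p

    def g_a(alpha: float):
        st = ws.side_state(alpha, "a")
        if st is None:
            return np.nan
        d = st["m"] - m_pre_a
        return d[1] - zeta_a * d[0]

    sols = []
    for ra in _scan_roots(g_a, _ALPHA_GRID):
        st_a = ws.side_state(ra, "a")

        def g_p(alpha: float):
            st = ws.side_state(alpha, "p", tip_x=st_a["tip"][0])
            if st is None:
                return np.nan
            d = st["m"] - m_pre_p
            return d[1] + zeta_p * d[0]

        for rp in _scan_roots(g_p, _ALPHA_GRID):
            st_p = ws.side_state(rp, "p", tip_x=st_a["tip"][0])
            r = meas.MAD_pre - st_a["x_loc"] - st_p["x_loc"]
            if not (0.0 <= r <= meas.MAD_pre):
                continue
            if st_a["lam"] < 1.0 or st_p["lam"] < 1.0:
                continue            # slack chorda: no tethered equilibrium
            sols.append({"a": st_a, "p": st_p, "r": r,
                         "zeta_a": zeta_a, "zeta_p": zeta_p})
    return sols


def _objective(sol: dict, meas: ValveMeasurements, kind: str = "max") -> float:
    T_a = sol["a"]["P"] / meas.material.A_ref
    T_p = sol["p"]["P"] / meas.material.A_ref
    return max(T_a, T_p) if kind == "max" else T_a + T_p


def _displacement_norm(sol: dict, preop: PreopConfiguration) -> float:
    ua = sol["a"]["m"] - preop.system.m_a
    up = sol["p"]["m"] - preop.system.m_p
    return float(np.linalg.norm(ua) + np.linalg.norm(up))


def _branch_fold(ws: _Workspace, side: str) -> dict:
    """Tethered state at the branch fold: the deepest-reaching equilibrium.

    Along the tethered branch the tip moves toward the midline and deepens
    as the inclination grows, until the chorda stress outruns the leaflet
    load and the equilibrium ceases (fold).  Located by bisection on the
    inclination between the last valid and first invalid grid points.
    """
    branch = ws.tethered_branch(side, 0.0)
    valid = [i for i, s in enumerate(branch) if s is not None]
    if not valid:
        raise PostopSolveError(f"annuloplasty-only: side '{side}' has no "
                               "tethered equilibrium at all")
    i = valid[-1]
    if i == len(branch) - 1:
        return branch[i]
    lo, hi = float(_ALPHA_GRID[i]), float(_ALPHA_GRID[i + 1])
    hint = branch[i]["theta"]
    best = branch[i]
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        st = ws.tethered_state(mid, side, hint=hint)
        if st is None:
            hi = mid
        else:
            lo, best, hint = mid, st, st["theta"]
    return best


def _state_at_depth(ws: _Workspace, side: str, y_target: float) -> dict | None:
    """Tethered state of one side whose tip depth equals y_target."""
    branch = [s for s in ws.tethered_branch(side, 0.0) if s is not None]
    if not branch:
        return None
    for j in range(len(branch) - 1):
        y0 = branch[j]["tip"][1] - y_target
        y1 = branch[j + 1]["tip"][1] - y_target
        if y0 == 0.0 or y0 * y1 < 0:
            hint = branch[j]["theta"]

            def f(a):
                st = ws.tethered_state(a, side, hint=hint)
                return np.nan if st is None else st["tip"][1] - y_target

            a_root = brentq(f, branch[j]["alpha"], branch[j + 1]["alpha"], xtol=1e-13)
            return ws.tethered_state(a_root, side, hint=hint)
    return None


def _solve_ra_only(ws: _Workspace) -> dict:
    """Annuloplasty-only: motionless papillary muscles, best-effort closure.

    With the muscles pinned wide, each leaflet can only follow its tethered
    equilibrium branch; the branches fold before the tips meet, so full
    coaptation is impossible on restriction alone.  The solution drives both
    tips to the common depth of maximal reach — the limiting side sits at
    its fold, the other matches its depth — leaving a horizontal coaptation
    gap (the persistent regurgitant orifice of annuloplasty alone under
    severe tethering).  Both chordae are then at their maximal tethering
    stretch, and the per-side restriction follows from the hinge-to-tip
    geometry.
    """
    meas = ws.meas
    fold_a = _branch_fold(ws, "a")
    fold_p = _branch_fold(ws, "p")
    # the side with the shallower maximal reach limits the shared depth
    if fold_a["tip"][1] <= fold_p["tip"][1]:
        st_a = fold_a
        st_p = _state_at_depth(ws, "p", fold_a["tip"][1])
    else:
        st_p = fold_p
        st_a = _state_at_depth(ws, "a", fold_p["tip"][1])
    if st_a is None or st_p is None:
        raise PostopSolveError(
            "annuloplasty-only: the leaflets' tethered branches share no "
            "common tip depth"
        )
    r_a = st_a["tip"][0] - st_a["x_loc"]
    r_p = meas.MAD_pre - st_p["tip"][0] - st_p["x_loc"]
    gap = float(st_p["tip"][0] - st_a["tip"][0])
    return {"a": st_a, "p": st_p, "r": r_a + r_p, "r_a": r_a, "r_p": r_p,
            "gap": gap}


def _solve_complete_pma(ws: _Workspace, ipd_target: float,
                        on_unreachable: str = "raise") -> dict:
    """Approximation to a prescribed IPD with one shared orientation zeta.

    When the prescription lies below the chordae-taut floor (no shared
    orientation reaches it), ``on_unreachable='nearest'`` substitutes the
    closest achievable distance instead of raising.
    """
    meas = ws.meas

    def best_at(zeta: float):
        sols = _solve_fixed_zeta(ws, zeta, zeta)
        if not sols:
            return None
        return min(sols, key=lambda s: _objective(s, meas))

    def ipd_of(zeta: float):
        best = best_at(zeta)
        if best is None:
            return np.nan
        return interpapillary_distance(best["a"]["m"], best["p"]["m"])

    zeta_grid = np.linspace(-5.0, 5.0, 81)
    roots = _scan_roots(lambda z: ipd_of(z) - ipd_target, zeta_grid)
    achieved = ipd_target
    if not roots:
        vals = np.array([ipd_of(z) for z in zeta_grid])
        if not np.isfinite(vals).any():
            raise PostopSolveError("complete approximation: no orientation converged")
        floor = float(np.nanmin(vals))
        if on_unreachable != "nearest":
            raise PostopSolveError(
                f"no shared orientation reaches the prescribed IPD {ipd_target} mm "
                f"(closest achievable ~{floor:.1f} mm); the taut chordae bound the "
                f"approximation"
            )
        from scipy.optimize import minimize_scalar
        i = int(np.nanargmin(vals))
        lo = float(zeta_grid[max(i - 1, 0)])
        hi = float(zeta_grid[min(i + 1, len(zeta_grid) - 1)])
        opt = minimize_scalar(ipd_of, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        roots = [float(opt.x)]
        achieved = float(opt.fun)
    candidates = []
    for z in roots:
        best = best_at(z)
        if best is not None:
            best = dict(best)
            best["ipd_achieved"] = achieved
            candidates.append(best)
    if not candidates:
        raise PostopSolveError("complete approximation: orientation root lost")
    return min(candidates, key=lambda s: _objective(s, meas))


# ---------------------------------------------------------------------------
# assembly and public API

def _assemble(sol: dict, preop: PreopConfiguration, meas: ValveMeasurements,
              scenario: Scenario, provenance: dict,
              r_a: float | None = None, r_p: float | None = None
              ) -> PostopConfiguration:
    """Build the full PostopConfiguration from a per-side solution dict."""
    st_a, st_p = sol["a"], sol["p"]
    mat = meas.material
    r = sol["r"]
    u_a = st_a["m"] - preop.system.m_a
    u_p = st_p["m"] - preop.system.m_p
    sol_a = el.solve_elastica(st_a["theta"], st_a["alpha"], meas.l_a, meas.B)
    sol_p = el.solve_elastica(st_p["theta"], st_p["alpha"], meas.l_p, meas.B)
    if scenario is Scenario.RA_ONLY:
        a_a = np.array([r_a, 0.0])
        a_p = np.array([meas.MAD_pre - r_p, 0.0])
    else:
        a_a = np.zeros(2)
        a_p = np.array([meas.MAD_pre - r, 0.0])
    system = SystemConfiguration(
        a_a=a_a, a_p=a_p,
        b_a=st_a["tip"], b_p=st_p["tip"], m_a=st_a["m"], m_p=st_p["m"],
        theta_a=st_a["theta"], theta_p=st_p["theta"],
        alpha_a=st_a["alpha"], alpha_p=st_p["alpha"],
        elastica_a=sol_a, elastica_p=sol_p,
        chorda_a=ChordaState.from_lengths(
            preop.L_c_a, float(np.linalg.norm(st_a["tip"] - st_a["m"])), mat),
        chorda_p=ChordaState.from_lengths(
            preop.L_c_p, float(np.linalg.norm(st_p["tip"] - st_p["m"])), mat),
    )
    if scenario is Scenario.RA_ONLY:
        res = _ra_only_residuals(sol, preop, meas)
    else:
        unknowns = (st_a["theta"], st_p["theta"], st_a["alpha"], st_p["alpha"],
                    float(u_a[0]), float(-u_p[0]), r)
        res = postop_residuals(unknowns, preop, meas,
                               sol.get("zeta_a"), sol.get("zeta_p"))
    surgical = SurgicalVariables(
        r=r, u_a=u_a, u_p=u_p,
        zeta_a=sol.get("zeta_a"), zeta_p=sol.get("zeta_p"),
        r_a=r_a, r_p=r_p,
    )
    return PostopConfiguration(
        system=system, surgical=surgical, scenario=scenario,
        P_po_a=st_a["P"], P_po_p=st_p["P"],
        lam_po_a=st_a["lam"], lam_po_p=st_p["lam"],
        M_po_a=st_a["M"], M_po_p=st_p["M"],
        T_po_a=st_a["P"] / mat.A_ref, T_po_p=st_p["P"] / mat.A_ref,
        MAD_po=meas.MAD_pre - r,
        IPD_po=interpapillary_distance(st_a["m"], st_p["m"]),
        residual_norm=float(np.max(np.abs(res))),
        provenance=provenance,
    )


def _ra_only_residuals(sol: dict, preop: PreopConfiguration,
                       meas: ValveMeasurements) -> np.ndarray:
    """Residuals of the decoupled annuloplasty-only system.

    Per side: node equilibrium and congruency; globally: the equal-tip-depth
    condition (scaled by MAD_pre).  The horizontal coaptation gap is an
    outcome, not a constraint.
    """
    mat = meas.material
    out = []
    for side, L_c in (("a", preop.L_c_a), ("p", preop.L_c_p)):
        st = sol[side]
        ch = ChordaState.from_lengths(L_c, float(np.linalg.norm(st["tip"] - st["m"])), mat)
        v = st["m"] - st["tip"]
        if side == "a":
            cong = (math.pi / 2 + st["alpha"]) - math.atan2(v[1], v[0])
        else:
            cong = (math.pi / 2 - st["alpha"]) - math.atan2(v[1], v[0])
        out += [
            (ch.sigma - ch.lam * st["P"] / mat.A_ref) / mat.c1,
            cong,
        ]
    out.append((sol["a"]["tip"][1] - sol["p"]["tip"][1]) / meas.MAD_pre)
    return np.array(out)


def solve_scenario(preop: PreopConfiguration, meas: ValveMeasurements,
                   scenario: Scenario | str,
                   zeta_pair: tuple[float, float] | None = None,
                   ipd_target: float = 10.0,
                   on_unreachable: str = "raise",
                   seed: int | None = None) -> PostopConfiguration:
    """Solve one surgical scenario from a finalised preoperative state.

    ``zeta_pair`` is required for OPTIMIZED_PMA (one fixed orientation pair;
    use :func:`optimize_pma` for the stress-minimising search).
    ``on_unreachable`` controls COMPLETE_PMA when the prescribed IPD lies
    below the chordae-taut floor: ``"raise"`` or ``"nearest"``.
    """
    scenario = Scenario(scenario) if not isinstance(scenario, Scenario) else scenario
    ws = _Workspace(preop, meas)
    if scenario is Scenario.OPTIMIZED_PMA:
        if zeta_pair is None:
            raise ValueError("OPTIMIZED_PMA requires zeta_pair; or call optimize_pma")
        sols = _solve_fixed_zeta(ws, *zeta_pair)
        if not sols:
            raise PostopSolveError(f"no solution at zeta={zeta_pair}")
        best = min(sols, key=lambda s: _objective(s, meas))
        return _assemble(best, preop, meas, scenario,
                         provenance={"zeta_pair": zeta_pair, "n_solutions": len(sols)})
    if scenario is Scenario.RA_ONLY:
        sol = _solve_ra_only(ws)
        return _assemble(sol, preop, meas, scenario,
                         provenance={"tip_depth": float(sol["a"]["tip"][1]),
                                     "coaptation_gap": sol["gap"]},
                         r_a=sol["r_a"], r_p=sol["r_p"])
    if scenario is Scenario.COMPLETE_PMA:
        sol = _solve_complete_pma(ws, ipd_target, on_unreachable=on_unreachable)
        return _assemble(sol, preop, meas, scenario,
                         provenance={"ipd_target": ipd_target,
                                     "ipd_achieved": sol.get("ipd_achieved", ipd_target),
                                     "zeta_shared": sol["zeta_a"]})
    raise ValueError(f"unhandled scenario {scenario}")


def optimize_pma(preop: PreopConfiguration, meas: ValveMeasurements,
                 seed: int | None = 0, n_draws: int = N_DRAWS_DEFAULT,
                 objective: str = "max",
                 zeta_range: tuple[float, float] = ZETA_RANGE,
                 tie_tolerance: float = TIE_TOLERANCE) -> PostopConfiguration:
    """Random orientation search minimising the postoperative chordae stress.

    ``n_draws`` orientation pairs (zeta_a, zeta_p) are sampled uniformly on
    ``zeta_range``; every converged solution is scored by the chordae nominal
    stress (``objective='max'``: worst chorda; ``'sum'``: total).  Because
    the stress is nearly invariant along the solution manifold, the draw of
    smallest total papillary displacement among those within
    ``tie_tolerance`` of the best objective is returned (surgical parsimony:
    large displacements load the ventricular wall).  Deterministic per seed.
    """
    if objective not in ("max", "sum"):
        raise ValueError(f"objective must be 'max' or 'sum', got {objective!r}")
    ws = _Workspace(preop, meas)
    rng = np.random.default_rng(seed)
    draws = rng.uniform(zeta_range[0], zeta_range[1], size=(n_draws, 2))
    candidates = []
    history = []
    for zeta_a, zeta_p in draws:
        sols = _solve_fixed_zeta(ws, zeta_a, zeta_p)
        if not sols:
            history.append({"zeta": (zeta_a, zeta_p), "objective": None})
            continue
        best = min(sols, key=lambda s: _objective(s, meas, objective))
        obj = _objective(best, meas, objective)
        history.append({"zeta": (zeta_a, zeta_p), "objective": obj})
        candidates.append((obj, _displacement_norm(best, preop), best))
    if not candidates:
        raise PostopSolveError(f"no orientation draw converged in {n_draws} draws")
    best_obj = min(c[0] for c in candidates)
    eligible = [c for c in candidates if c[0] <= best_obj * (1.0 + tie_tolerance)]
    chosen = min(eligible, key=lambda c: c[1])
    provenance = {
        "seed": seed, "n_draws": n_draws, "objective": objective,
        "best_objective": best_obj, "chosen_objective": chosen[0],
        "n_converged": len(candidates), "history": history,
    }
    return _assemble(chosen[2], preop, meas, Scenario.OPTIMIZED_PMA, provenance)


def indicators(preop: PreopConfiguration, postop: PostopConfiguration) -> IndicatorSet:
    """Post/pre effectiveness ratios Mr, Tr, lambda_r per leaflet."""
    for name, v in (("M_pre_a", preop.M_pre_a), ("M_pre_p", preop.M_pre_p),
                    ("T_pre_a", preop.T_pre_a), ("T_pre_p", preop.T_pre_p),
                    ("lam_pre_a", preop.lam_pre_a), ("lam_pre_p", preop.lam_pre_p)):
        if v == 0:
            raise ZeroDivisionError(f"preoperative denominator {name} is zero")
    return IndicatorSet(
        Mr_a=postop.M_po_a / preop.M_pre_a,
        Mr_p=postop.M_po_p / preop.M_pre_p,
        Tr_a=postop.T_po_a / preop.T_pre_a,
        Tr_p=postop.T_po_p / preop.T_pre_p,
        lr_a=postop.lam_po_a / preop.lam_pre_a,
        lr_p=postop.lam_po_p / preop.lam_pre_p,
    )


def compare_scenarios(preop: PreopConfiguration, meas: ValveMeasurements,
                      seed: int | None = 0, n_draws: int = N_DRAWS_DEFAULT,
                      ipd_target: float = 10.0) -> dict:
    """All three scenarios from the same preoperative state.

    Returns {scenario: {"postop": ..., "indicators": ...}} with per-scenario
    failures reported under an "error" key instead of aborting the rest.
    An unreachable complete-approximation prescription falls back to the
    nearest achievable distance (recorded in the provenance).
    """
    out = {}
    for scenario in Scenario:
        try:
            if scenario is Scenario.OPTIMIZED_PMA:
                po = optimize_pma(preop, meas, seed=seed, n_draws=n_draws)
            else:
                po = solve_scenario(preop, meas, scenario, ipd_target=ipd_target,
                                    on_unreachable="nearest")
            out[scenario] = {"postop": po, "indicators": indicators(preop, po)}
        except (PostopSolveError, ValueError) as exc:
            out[scenario] = {"error": str(exc)}
    return out
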