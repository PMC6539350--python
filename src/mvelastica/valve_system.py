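"""Planar assembly of two leaflets, two chordae and two papillary muscles.

Global frame
------------
The anterior annular hinge sits at the origin, the posterior hinge at
``(MAD, 0)`` (moved to ``(MAD - r, 0)`` by an annular restriction r), and y
grows toward the apex.  The anterior leaflet local frame coincides with the
global one; the posterior leaflet is solved in its own local frame (x toward
the opposite leaflet) and mirrored about its hinge when assembled.

Chorda angles ``alpha`` are measured from the apical y-axis and tilt *away*
from the valve midline — the tethering direction of displaced papillary
muscles.  The congruency conditions coupling leaflet and chorda read

    pi/2 + alpha_a = arg(m_a - b_a),      pi/2 - alpha_p = arg(m_p - b_p)

with ``arg`` the counterclockwise angle from +x in (-pi, pi], ``b`` the
leaflet free edge and ``m`` the papillary head.  Consistently, the papillary
heads sit at

    m_a = (x_l^a - (h_a - y_l^a) tan(alpha_a), h_a)
    m_p = (MAD - x_l^p + (h_p - y_l^p) tan(alpha_p), h_p)

where h is the annulus-to-papillary-head height (papillary y-coordinate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .chordae import ChordaMaterial, ChordaState
from .elastica import ElasticaSolution

__all__ = [
    "ValveMeasurements",
    "SystemConfiguration",
    "pm_position_anterior",
    "pm_position_posterior",
    "interpapillary_distance",
    "chorda_congruency_residual",
    "node_equilibrium_residual",
]

#: Reference chorda constitutive constants (literature uniaxial tests).
REFERENCE_MATERIAL = ChordaMaterial(c1=352.4, c2=0.1907, A_ref=0.197)


@dataclass(frozen=True)
class ValveMeasurements:
    """Clinical measurements and model constants defining one patient.

    Angles are stored in radians; lengths in mm, stiffness in mN mm^2.
    ``TH_opt`` is the surgical target coaptation height, strictly below the
    preoperative tenting height ``TH_pre``.
    """

    MAD_pre: float      # mitral annular diameter [mm]
    IPD_pre: float      # end-diastolic interpapillary distance [mm]
    TH_pre: float       # tenting height [mm]
    TH_opt: float       # target coaptation height [mm]
    delta_a: float      # anterior leaflet angle [rad]
    delta_p: float      # posterior leaflet angle [rad]
    h_a: float          # annulus -> anterior papillary head [mm]
    h_p: float          # annulus -> posterior papillary head [mm]
    l_a: float          # anterior leaflet length [mm]
    l_p: float          # posterior leaflet length [mm]
    B: float            # leaflet bending stiffness [mN mm^2]
    material: ChordaMaterial = REFERENCE_MATERIAL

    def __post_init__(self) -> None:
        for name in ("MAD_pre", "IPD_pre", "TH_pre", "TH_opt", "h_a", "h_p",
                     "l_a", "l_p", "B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("delta_a", "delta_p"):
            d = getattr(self, name)
            if not (0.0 < d < math.pi / 2):
                raise ValueError(f"{name} must lie in (0, 90) degrees, got {math.degrees(d):.1f} deg")
        if not self.TH_opt < self.TH_pre:
            raise ValueError(
                f"target coaptation height TH_opt={self.TH_opt} must be below TH_pre={self.TH_pre}"
            )

    @classmethod
    def reference_case(cls) -> "ValveMeasurements":
        """The reference ischemic-regurgitation case used throughout.

        Cohort-mean echocardiographic values with the case-study annular
        diameter (41 mm) and posterior papillary height (35 mm).
        """
        return cls(
            MAD_pre=41.0, IPD_pre=44.6, TH_pre=12.4, TH_opt=6.8,
            delta_a=math.radians(32.6), delta_p=math.radians(56.8),
            h_a=45.0, h_p=35.0, l_a=18.0, l_p=13.0, B=500.0,
            material=REFERENCE_MATERIAL,
        )

    def with_(self, **kwargs) -> "ValveMeasurements":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SystemConfiguration:
    """Geometric and mechanical state of the assembled valve at one phase.

    All points are 2D global coordinates in mm.  ``elastica_a/p`` carry the
    per-leaflet closed-form solutions (local frames); ``chorda_a/p`` the
    chorda states once reference lengths are known (None during the purely
    geometric identification stage).
    """

    a_a: np.ndarray         # anterior annular joint
    a_p: np.ndarray         # posterior annular joint
    b_a: np.ndarray         # anterior free edge
    b_p: np.ndarray         # posterior free edge
    m_a: np.ndarray         # anterior papillary head
    m_p: np.ndarray         # posterior papillary head
    theta_a: float          # leaflet end slopes [rad]
    theta_p: float
    alpha_a: float          # chorda inclinations [rad]
    alpha_p: float
    elastica_a: ElasticaSolution
    elastica_p: ElasticaSolution
    chorda_a: ChordaState | None = None
    chorda_p: ChordaState | None = None

    @property
    def interpapillary_distance(self) -> float:
        return interpapillary_distance(self.m_a, self.m_p)


def pm_position_anterior(tip, alpha_a: float, h_a: float) -> np.ndarray:
    """Anterior papillary head from the tip, chorda angle and height.

    The chorda leaves the tip apically, tilted by ``alpha_a`` away from the
    midline, and ends on the horizontal line y = h_a.
    """
    tip = np.asarray(tip, dtype=float)
    if h_a <= tip[1]:
        raise ValueError(
            f"papillary head height h={h_a} must exceed the tip depth y={tip[1]}"
        )
    return np.array([tip[0] - (h_a - tip[1]) * math.tan(alpha_a), h_a])


def pm_position_posterior(tip_local, alpha_p: float, h_p: float, MAD: float) -> np.ndarray:
    """Posterior papillary head; mirror image of the anterior construction.

    ``tip_local`` is the posterior tip in its leaflet-local frame; the global
    tip is (MAD - x_l, y_l).
    """
    tip_local = np.asarray(tip_local, dtype=float)
    if h_p <= tip_local[1]:
        raise ValueError(
            f"papillary head height h={h_p} must exceed the tip depth y={tip_local[1]}"
        )
    return np.array(
        [MAD - tip_local[0] + (h_p - tip_local[1]) * math.tan(alpha_p), h_p]
    )


def interpapillary_distance(m_a, m_p) -> float:
    """Euclidean distance between the two papillary heads [mm]."""
    d = np.asarray(m_a, dtype=float) - np.asarray(m_p, dtype=float)
    return float(np.hypot(d[0], d[1]))


def chorda_congruency_residual(config: SystemConfiguration) -> tuple[float, float]:
    """Angular mismatch [rad] between chorda inclinations and chorda vectors.

    Zero when each chorda vector m - b actually points along the direction
    implied by its alpha.
    """
    va = config.m_a - config.b_a
    vp = config.m_p - config.b_p
    res_a = (math.pi / 2 + config.alpha_a) - math.atan2(va[1], va[0])
    res_p = (math.pi / 2 - config.alpha_p) - math.atan2(vp[1], vp[0])
    return res_a, res_p


def node_equilibrium_residual(config: SystemConfiguration, P_a: float, P_p: float,
                              A_ref: float = REFERENCE_MATERIAL.A_ref
                              ) -> tuple[float, float]:
    """Free-edge force balance sigma - lam P / A_ref per chorda [mN/mm^2]."""
    if config.chorda_a is None or config.chorda_p is None:
        raise ValueError("chorda states not set; equilibrium undefined")
    res_a = config.chorda_a.sigma - config.chorda_a.lam * P_a / A_ref
    res_p = config.chorda_p.sigma - config.chorda_p.lam * P_p / A_ref
    return res_a, res_p
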