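"""Fung-type hyperelastic chordae tendineae.

A chorda is a one-dimensional incompressible element loaded in uniaxial
tension.  With stretch ``lam = l_c / L_c`` (current over reference length)
and Green strain ``eps = (lam^2 - 1)/2``, the strain energy density is

    psi(eps) = (c1/c2) (exp(c2 eps) - 1) - c1 eps

so the tensile Cauchy stress is ``sigma = dpsi/deps = c1 (exp(c2 eps) - 1)``
and the nominal stress (edge load per reference cross-section) relates to it
through incompressibility as ``sigma = T lam`` with ``T = P / A_ref``.

Chordae carry tension only: a configuration with ``lam < 1`` is slack and
transmits no force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "ChordaMaterial",
    "ChordaState",
    "green_strain",
    "cauchy_stress",
    "strain_energy",
    "nominal_stress",
    "equilibrium_stretch",
    "reference_length",
]


@dataclass(frozen=True)
class ChordaMaterial:
    """Fung constants: c1 [mN/mm^2], c2 [-], reference area A_ref [mm^2]."""

    c1: float
    c2: float
    A_ref: float

    def __post_init__(self) -> None:
        if not (self.c1 > 0 and self.c2 > 0 and self.A_ref > 0):
            raise ValueError(f"chorda constants must be positive: {self}")


@dataclass(frozen=True)
class ChordaState:
    """Stretch/strain/stress state of one chorda.

    ``slack`` marks a compressively shortened chorda (lam < 1); its stresses
    are zero by the tension-only constitutive assumption.
    """

    L_c: float      # reference length [mm]
    l_c: float      # current length [mm]
    lam: float      # stretch [-]
    eps: float      # Green strain [-]
    sigma: float    # Cauchy stress [mN/mm^2]
    T: float        # nominal stress [mN/mm^2]
    slack: bool = False

    @classmethod
    def from_lengths(cls, L_c: float, l_c: float, material: ChordaMaterial) -> "ChordaState":
        if L_c <= 0 or l_c <= 0:
            raise ValueError("chorda lengths must be positive")
        lam = l_c / L_c
        if lam < 1.0:
            return cls(L_c=L_c, l_c=l_c, lam=lam, eps=green_strain(lam),
                       sigma=0.0, T=0.0, slack=True)
        eps = green_strain(lam)
        sigma = cauchy_stress(eps, material)
        return cls(L_c=L_c, l_c=l_c, lam=lam, eps=eps, sigma=sigma, T=sigma / lam)


def green_strain(lam: float) -> float:
    """eps = (lam^2 - 1) / 2 for stretch lam > 0."""
    if lam <= 0:
        raise ValueError(f"stretch must be positive, got {lam}")
    return 0.5 * (lam * lam - 1.0)


def cauchy_stress(eps: float, material: ChordaMaterial) -> float:
    """sigma = c1 (exp(c2 eps) - 1); zero at eps = 0, strictly increasing."""
    return material.c1 * math.expm1(material.c2 * eps)


def strain_energy(eps: float, material: ChordaMaterial) -> float:
    """psi = (c1/c2)(exp(c2 eps) - 1) - c1 eps; non-negative and convex."""
    return (material.c1 / material.c2) * math.expm1(material.c2 * eps) - material.c1 * eps


def nominal_stress(sigma: float, lam: float) -> float:
    """First Piola (nominal) stress T = sigma / lam."""
    return sigma / lam


def equilibrium_stretch(P: float, material: ChordaMaterial,
                        lam_max: float = 3.0, grow: float = 1.5,
                        max_growth: int = 40) -> float:
    """Stretch at which the chorda balances an end load P [mN].

    Solves ``c1 (exp(c2 (lam^2-1)/2) - 1) = lam P / A_ref`` for lam >= 1.
    The left side grows exponentially and the right linearly, so the root is
    unique; the bracket [1, lam_max] is grown geometrically if needed.
    """
    if P < 0:
        raise ValueError(f"chordae cannot push: P={P}")
    if P == 0:
        return 1.0

    def residual(lam: float) -> float:
        return cauchy_stress(green_strain(lam), material) - lam * P / material.A_ref

    hi = lam_max
    for _ in range(max_growth):
        if residual(hi) > 0:
            return brentq(residual, 1.0, hi, xtol=1e-14, rtol=8.9e-16)
        hi *= grow
    raise ValueError(f"no equilibrium stretch in [1, {hi:.3g}] for P={P} mN")


def reference_length(l_c_pre: float, lam_pre: float) -> float:
    """Pull back the observed preoperative length: L_c = l_c_pre / lam_pre."""
    if lam_pre < 1.0:
        raise ValueError(f"preoperative stretch must be >= 1, got {lam_pre}")
    return l_c_pre / lam_pre
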