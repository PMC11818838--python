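"""Incompressible second-order Yeoh constitutive law for articular cartilage.

The strain-energy density depends only on the first deviatoric invariant
``I1`` of the right Cauchy-Green tensor:

    W(I1) = C10 * (I1 - 3) + C20 * (I1 - 3)**2        [MPa]

with material constants ``C10 > 0`` and ``C20 >= 0``.  Cartilage is treated
as exactly incompressible, so under uniaxial loading along the first
principal axis the stretches are ``(lam, lam**-0.5, lam**-0.5)`` and

    I1(lam) = lam**2 + 2 / lam .

Sign convention, used everywhere downstream: compression is ``lam < 1``
with negative axial Cauchy stress; contact pressure is ``-sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "YeohParams",
    "UniaxialState",
    "first_invariant_uniaxial",
    "strain_energy",
    "uniaxial_cauchy_stress",
    "uniaxial_nominal_stress",
    "uniaxial_stiffness",
    "uniaxial_nominal_stiffness",
]


@dataclass(frozen=True)
class YeohParams:
    """Yeoh material constants in MPa."""

    c10: float
    c20: float = 0.0

    def __post_init__(self) -> None:
        if not self.c10 > 0.0:
            raise ValueError(f"C10 must be positive, got {self.c10}")
        if self.c20 < 0.0:
            raise ValueError(f"C20 must be non-negative, got {self.c20}")


@dataclass(frozen=True)
class UniaxialState:
    """Principal stretch and first deviatoric invariant of a uniaxial state."""

    lam: float
    i1: float

    def __post_init__(self) -> None:
        if not self.lam > 0.0:
            raise ValueError(f"stretch must be positive, got {self.lam}")
        if self.i1 < 3.0 - 1e-12:
            raise ValueError(f"I1 must be >= 3, got {self.i1}")


def first_invariant_uniaxial(lam: float) -> float:
    """First deviatoric invariant for incompressible uniaxial loading.

    ``I1 = lam**2 + 2/lam``; minimum 3 at ``lam = 1``.
    """
    if not lam > 0.0:
        raise ValueError(f"stretch must be positive, got {lam}")
    return lam * lam + 2.0 / lam


def strain_energy(p: YeohParams, i1: float) -> float:
    """Strain-energy density W(I1) in MPa; zero iff undeformed (I1 = 3)."""
    if i1 < 3.0 - 1e-12:
        raise ValueError(f"I1 must be >= 3, got {i1}")
    x = max(i1 - 3.0, 0.0)
    return p.c10 * x + p.c20 * x * x


def uniaxial_cauchy_stress(p: YeohParams, lam: float) -> float:
    """Axial Cauchy stress (MPa) of the incompressible uniaxial response.

    sigma = 2 * (lam**2 - 1/lam) * (C10 + 2*C20*(I1 - 3)),
    equal to lam * dW/dlam along the incompressible uniaxial path.
    Negative in compression (lam < 1), zero at lam = 1.
    """
    if not lam > 0.0:
        raise ValueError(f"stretch must be positive, got {lam}")
    x = first_invariant_uniaxial(lam) - 3.0
    return 2.0 * (lam * lam - 1.0 / lam) * (p.c10 + 2.0 * p.c20 * x)


def uniaxial_nominal_stress(p: YeohParams, lam: float) -> float:
    """Nominal (first Piola-Kirchhoff) axial stress, N = sigma / lam (MPa).

    This is the force per unit *reference* cross-sectional area: an
    incompressible column widens by the area factor 1/lam as it shortens,
    so N = dW/dlam along the uniaxial path.  The contact solver balances
    and integrates this traction over the undeformed contact patch.
    """
    return uniaxial_cauchy_stress(p, lam) / lam


def uniaxial_stiffness(p: YeohParams, lam: float) -> float:
    """Analytic d(sigma)/d(lam) of the uniaxial Cauchy stress (MPa).

    Used by the contact solver's Newton iteration.  At lam = 1 this equals
    6*C10, the incompressible small-strain Young's modulus.
    """
    if not lam > 0.0:
        raise ValueError(f"stretch must be positive, got {lam}")
    x = lam * lam + 2.0 / lam - 3.0
    g = p.c10 + 2.0 * p.c20 * x
    dx = 2.0 * lam - 2.0 / (lam * lam)
    return 2.0 * (2.0 * lam + 1.0 / (lam * lam)) * g + 2.0 * (
        lam * lam - 1.0 / lam
    ) * 2.0 * p.c20 * dx


def uniaxial_nominal_stiffness(p: YeohParams, lam: float) -> float:
    """Analytic d(N)/d(lam) of the nominal uniaxial stress (MPa)."""
    sigma = uniaxial_cauchy_stress(p, lam)
    return (uniaxial_stiffness(p, lam) - sigma / lam) / lam
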