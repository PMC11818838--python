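"""Layered sphere-plane cartilage contact via a nonlinear elastic foundation.

The condylar interface is idealised as a rigid sphere (femur, R = 40 mm)
pressed into a rigid plane (tibia), each backed by a thin incompressible
Yeoh cartilage layer (2.3 mm femoral, 2.1 mm tibial).  Because the layers
are thin compared with the sphere radius, every surface point is treated as
an independent column of the two layers in series (a nonlinear Winkler
foundation): each column carries the incompressible uniaxial Yeoh response
at the stretch that accommodates the local interpenetration, the two layers
share one traction, and bone backing is rigid.  Because an incompressible
column widens by the area factor 1/lam as it shortens, the force it
transmits per unit *reference* patch area (the quantity the radial
quadrature integrates) is the nominal traction N = sigma/lam, i.e. the
Cauchy stress acting on the column's current cross-section.

The total force at a prescribed indentation ``delta`` is the pressure
integrated over the circular contact patch using the exact sphere profile:

    u(r) = delta - (R - sqrt(R**2 - r**2)),   a = sqrt(delta * (2R - delta))
    F(delta) = integral_0^a p(u(r)) * 2*pi*r dr

solved on a fixed 400-node radial trapezoid grid.  The output of the model
is the force-indentation curve sampled at 20 equal steps up to 1.00 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .materials import (
    YeohParams,
    uniaxial_cauchy_stress,
    uniaxial_nominal_stress,
)

__all__ = [
    "CartilageLayer",
    "ContactPairSpec",
    "ForceIndentationCurve",
    "ContactConvergenceError",
    "layer_compression",
    "column_pressure",
    "indentation_force",
    "compute_curve",
    "eval_curve",
    "write_curve_csv",
    "read_curve_csv",
]

#: smallest admissible stretch; beyond this the thin-layer model is invalid
LAM_MIN = 0.2
#: absolute tolerance on the stretch root (layer_compression)
LAM_TOL = 1e-12
#: absolute tolerance on the shared column pressure, MPa
PRESSURE_TOL = 1e-10
#: radial quadrature nodes for the patch integral
N_RADIAL = 400
#: upper bound of the validated indentation range, mm
DELTA_MAX_VALID = 1.05


class ContactConvergenceError(RuntimeError):
    """Raised when the column solver leaves the model's validity range."""


@dataclass(frozen=True)
class CartilageLayer:
    """One cartilage layer: thickness in mm and its Yeoh material."""

    thickness: float
    material: YeohParams

    def __post_init__(self) -> None:
        if not self.thickness > 0.0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")


@dataclass(frozen=True)
class ContactPairSpec:
    """Geometry and materials of one condylar sphere-plane pair.

    The bone modulus/Poisson fields document the backing the foundation
    model treats as rigid (bone compliance has negligible effect on this
    interface); they do not enter the solution.
    """

    sphere_radius: float
    femoral: CartilageLayer
    tibial: CartilageLayer
    bone_modulus: float = 17200.0
    bone_poisson: float = 0.39

    def __post_init__(self) -> None:
        if self.sphere_radius <= self.femoral.thickness + self.tibial.thickness:
            raise ValueError("sphere radius must exceed the total cartilage thickness")

    @property
    def total_thickness(self) -> float:
        return self.femoral.thickness + self.tibial.thickness


@dataclass(frozen=True)
class ForceIndentationCurve:
    """Solved indentation response: ascending mm grid vs. forces in N."""

    indentations: np.ndarray
    forces: np.ndarray

    def __post_init__(self) -> None:
        ind = np.asarray(self.indentations, dtype=float)
        frc = np.asarray(self.forces, dtype=float)
        if ind.shape != frc.shape or ind.ndim != 1 or ind.size < 2:
            raise ValueError("indentations and forces must be equal-length 1-d grids")
        if ind[0] != 0.0 or frc[0] != 0.0:
            raise ValueError("curve must be anchored at (0, 0)")
        if np.any(np.diff(ind) <= 0.0):
            raise ValueError("indentation grid must be strictly ascending")
        if np.any(np.diff(frc) < 0.0):
            raise ValueError("forces must be nondecreasing")
        object.__setattr__(self, "indentations", ind)
        object.__setattr__(self, "forces", frc)


def layer_compression(layer: CartilageLayer, p: float) -> float:
    """Thickness loss (mm) of one layer under uniform pressure p (MPa).

    The pressure is the force per unit reference area of the column, so the
    balance is ``-uniaxial_nominal_stress(material, lam) = p``; the unique
    root ``lam in (LAM_MIN, 1]`` gives the compression ``t * (1 - lam)``.
    """
    if p < 0.0:
        raise ValueError(f"pressure must be non-negative, got {p}")
    if p == 0.0:
        return 0.0
    m = layer.material
    if -uniaxial_nominal_stress(m, LAM_MIN) <= p:
        raise ContactConvergenceError(
            f"pressure {p} MPa drives the stretch below {LAM_MIN}; "
            "indentation beyond model validity"
        )
    lam = brentq(
        lambda s: -uniaxial_nominal_stress(m, s) - p,
        LAM_MIN,
        1.0,
        xtol=LAM_TOL,
    )
    return layer.thickness * (1.0 - lam)


def column_pressure(spec: ContactPairSpec, u: float) -> float:
    """Pressure (MPa) carried by one column of the two layers in series.

    Returns the p >= 0 with
    ``layer_compression(femoral, p) + layer_compression(tibial, p) = u``.
    """
    t_total = spec.total_thickness
    if not 0.0 <= u < t_total:
        raise ValueError(f"interpenetration {u} outside [0, {t_total}) mm")
    if u == 0.0:
        return 0.0
    p_hi = 0.999999 * min(
        -uniaxial_nominal_stress(spec.femoral.material, LAM_MIN),
        -uniaxial_nominal_stress(spec.tibial.material, LAM_MIN),
    )

    def residual(p: float) -> float:
        return (
            layer_compression(spec.femoral, p)
            + layer_compression(spec.tibial, p)
            - u
        )

    if residual(p_hi) < 0.0:
        raise ContactConvergenceError(
            f"interpenetration {u} mm beyond the validity of the column model"
        )
    return brentq(residual, 0.0, p_hi, xtol=PRESSURE_TOL)


def _column_pressures(spec: ContactPairSpec, u: np.ndarray) -> np.ndarray:
    """Vectorised column pressures for an array of interpenetrations (mm).

    Newton iteration on the two layer stretches (equal nominal traction,
    compressions summing to u), clipped to the admissible stretch interval.
    Falls back to the scalar bracketed solver for any column that fails to
    converge.
    """
    u = np.asarray(u, dtype=float)
    mf, mt = spec.femoral.material, spec.tibial.material
    tf, tt = spec.femoral.thickness, spec.tibial.thickness
    lf = np.clip(1.0 - u / (tf + tt), LAM_MIN + 1e-3, 1.0)
    lt = lf.copy()
    active = u > 0.0
    for _ in range(60):
        sf = _nominal_arr(mf, lf)
        st = _nominal_arr(mt, lt)
        g1 = sf - st
        g2 = tf * (1.0 - lf) + tt * (1.0 - lt) - u
        if np.all(
            (~active)
            | ((np.abs(g1) < 1e-11) & (np.abs(g2) < 1e-12))
        ):
            break
        dsf = _nominal_stiffness_arr(mf, lf)
        dst = _nominal_stiffness_arr(mt, lt)
        det = dsf * (-tt) - (-dst) * (-tf)
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        dlf = (g1 * (-tt) - (-dst) * g2) / det
        dlt = (dsf * g2 - g1 * (-tf)) / det
        lf = np.clip(lf - np.where(active, dlf, 0.0), LAM_MIN + 1e-6, 1.0)
        lt = np.clip(lt - np.where(active, dlt, 0.0), LAM_MIN + 1e-6, 1.0)
    p = np.where(active, -_nominal_arr(mf, lf), 0.0)
    # final residual check; repair stragglers with the scalar solver
    check = tf * (1.0 - lf) + tt * (1.0 - lt) - u
    bad = active & (np.abs(check) > 1e-9)
    if np.any(bad):
        for i in np.flatnonzero(bad):
            p[i] = column_pressure(spec, float(u[i]))
    return np.maximum(p, 0.0)


def _cauchy_arr(m: YeohParams, lam: np.ndarray) -> np.ndarray:
    x = lam * lam + 2.0 / lam - 3.0
    return 2.0 * (lam * lam - 1.0 / lam) * (m.c10 + 2.0 * m.c20 * x)


def _nominal_arr(m: YeohParams, lam: np.ndarray) -> np.ndarray:
    return _cauchy_arr(m, lam) / lam


def _nominal_stiffness_arr(m: YeohParams, lam: np.ndarray) -> np.ndarray:
    x = lam * lam + 2.0 / lam - 3.0
    g = m.c10 + 2.0 * m.c20 * x
    dx = 2.0 * lam - 2.0 / (lam * lam)
    dsig = 2.0 * (2.0 * lam + 1.0 / (lam * lam)) * g + 2.0 * (
        lam * lam - 1.0 / lam
    ) * 2.0 * m.c20 * dx
    return (dsig - _cauchy_arr(m, lam) / lam) / lam


def indentation_force(
    spec: ContactPairSpec, delta: float, n_radial: int = N_RADIAL
) -> float:
    """Total contact force (N) at indentation delta (mm).

    Integrates the column pressure over the contact patch with the exact
    sphere profile on an ``n_radial``-node trapezoid grid.  Pressures are in
    MPa = N/mm^2 and lengths in mm, so the integral is directly in N.
    """
    if delta < 0.0:
        raise ValueError(f"indentation must be non-negative, got {delta}")
    if delta > DELTA_MAX_VALID + 1e-12:
        raise ValueError(
            f"indentation {delta} mm beyond the validated range "
            f"({DELTA_MAX_VALID} mm)"
        )
    if delta == 0.0:
        return 0.0
    r_max = np.sqrt(delta * (2.0 * spec.sphere_radius - delta))
    r = np.linspace(0.0, r_max, n_radial)
    u = delta - (spec.sphere_radius - np.sqrt(spec.sphere_radius**2 - r * r))
    u = np.clip(u, 0.0, None)
    p = _column_pressures(spec, u)
    return float(np.trapezoid(p * 2.0 * np.pi * r, r))


def compute_curve(
    spec: ContactPairSpec, delta_max: float = 1.00, n_steps: int = 20
) -> ForceIndentationCurve:
    """Force-indentation curve on the grid {0, delta_max/n_steps, ..., delta_max}."""
    if not delta_max > 0.0:
        raise ValueError("delta_max must be positive")
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    deltas = np.linspace(0.0, delta_max, n_steps + 1)
    forces = np.array([indentation_force(spec, float(d)) for d in deltas])
    return ForceIndentationCurve(deltas, forces)


def eval_curve(curve: ForceIndentationCurve, delta: float) -> float:
    """Piecewise-linear force at any indentation.

    Zero at and below zero indentation (no tension through contact); linear
    interpolation inside the grid; linear extrapolation along the last
    segment beyond it, which keeps the curve continuous when a dynamic
    simulation momentarily overshoots the solved range.
    """
    if delta <= 0.0:
        return 0.0
    ind, frc = curve.indentations, curve.forces
    if delta <= ind[-1]:
        return float(np.interp(delta, ind, frc))
    slope = (frc[-1] - frc[-2]) / (ind[-1] - ind[-2])
    return float(frc[-1] + slope * (delta - ind[-1]))


def write_curve_csv(curve: ForceIndentationCurve, path: str | Path) -> None:
    """Write a curve as a two-column CSV ``indentation_mm, force_N``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("indentation_mm,force_N\n")
        for d, f in zip(curve.indentations, curve.forces):
            fh.write(f"{d:.6f},{f:.8f}\n")


def read_curve_csv(path: str | Path) -> ForceIndentationCurve:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return ForceIndentationCurve(data[:, 0], data[:, 1])
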