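"""Planar hybrid tibiofemoral model.

A rigid femur moves in the sagittal plane above a fixed tibia.  Four
tension-only nonlinear cables stand in for the cruciate and collateral
ligaments (ACL, PCL, MCL, LCL); bone-on-bone contact through cartilage is
carried by two condylar sphere-plane pairs whose force-indentation curves
come from the layered contact solver.  Dynamics are integrated with the
semi-implicit (symplectic) Euler method at a 0.001 s step while a stepped
external moment drives the joint into flexion or extension; global viscous
damping lets every moment plateau settle to equilibrium.

Conventions
-----------
* Tibia frame: origin on the tibial plateau, x pointing posteriorly,
  y pointing proximally (up).  The plateau is the line y = 0 with outward
  normal (0, 1).
* Knee angle theta: 0 deg at full extension, increasing with flexion.
  theta is the femur's rotational coordinate; femoral attachment points are
  given in the femur frame at full extension and rotate clockwise (posterior
  roll) as theta grows.
* A positive external moment M_ext extends the knee (drives theta down), a
  negative one flexes it, matching a moment protocol running 0 -> +3.5 Nm
  in extension and 0 -> -3.5 Nm in flexion.  The generalized torque
  conjugate to theta is therefore -M_ext.
* Units: SI internally (m, N, rad, s); mm and deg at every interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import root

from .contact import ForceIndentationCurve, eval_curve

__all__ = [
    "Ligament",
    "KneeModel",
    "PlanarState",
    "LoadProtocol",
    "SimulationResult",
    "IntegrationError",
    "ligament_force",
    "contact_state",
    "net_wrench",
    "step_semi_implicit",
    "run_branch",
    "angular_range",
    "find_static_equilibrium",
]

LIGAMENT_NAMES = ("ACL", "PCL", "MCL", "LCL")


class IntegrationError(RuntimeError):
    """Raised when a branch simulation diverges."""


@dataclass(frozen=True)
class Ligament:
    """Tension-only nonlinear cable.

    Attachments are 2-d points in mm: ``femoral`` in the femur frame at full
    extension (relative to the condyle centre), ``tibial`` in the tibia
    frame.  ``stiffness`` is the linear-branch stiffness in N per unit
    strain; ``rest_length`` (mm) is the slack length below which the cable
    carries no force; ``toe_strain`` is the quadratic-toe parameter.
    """

    name: str
    femoral: tuple[float, float]
    tibial: tuple[float, float]
    stiffness: float
    rest_length: float
    toe_strain: float = 0.03

    def __post_init__(self) -> None:
        if self.name not in LIGAMENT_NAMES:
            raise ValueError(f"unknown ligament name {self.name!r}")
        if not self.stiffness > 0.0:
            raise ValueError("stiffness must be positive")
        if not self.rest_length > 0.0:
            raise ValueError("rest length must be positive")


@dataclass(frozen=True)
class KneeModel:
    """Planar rigid-femur knee model (lengths in mm, angles in deg)."""

    ligaments: tuple[Ligament, Ligament, Ligament, Ligament]
    condyle_centers: tuple[tuple[float, float], tuple[float, float]]
    condyle_radius: float
    plateau_point: tuple[float, float]
    plateau_normal: tuple[float, float]
    mass: float  # kg
    inertia: float  # kg m^2
    damping_translational: float  # N s / m
    damping_rotational: float  # N m s / rad
    initial_pose: tuple[float, float, float]  # (x mm, y mm, theta deg)

    def __post_init__(self) -> None:
        if tuple(l.name for l in self.ligaments) != LIGAMENT_NAMES:
            raise ValueError(f"ligaments must be ordered {LIGAMENT_NAMES}")
        if not self.condyle_radius > 0.0:
            raise ValueError("condyle radius must be positive")
        n = math.hypot(*self.plateau_normal)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("plateau normal must be a unit vector")

    def ligament(self, name: str) -> Ligament:
        return self.ligaments[LIGAMENT_NAMES.index(name)]


@dataclass
class PlanarState:
    """Femur state: q = (x m, y m, theta rad), v = (xdot, ydot, thetadot)."""

    q: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).copy()
        self.v = np.asarray(self.v, dtype=float).copy()
        if self.q.shape != (3,) or self.v.shape != (3,):
            raise ValueError("q and v must be length-3 vectors")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.v))):
            raise ValueError("state must be finite")

    @classmethod
    def from_pose(cls, pose_mm_deg: tuple[float, float, float]) -> "PlanarState":
        x, y, th = pose_mm_deg
        return cls(
            q=np.array([x * 1e-3, y * 1e-3, math.radians(th)]),
            v=np.zeros(3),
        )

    @property
    def theta_deg(self) -> float:
        return math.degrees(self.q[2])


@dataclass(frozen=True)
class LoadProtocol:
    """Stepped external-moment protocol for one branch."""

    direction: str  # "extension" or "flexion"
    m_max: float = 3.5  # Nm
    n_steps: int = 5
    duration: float = 16.0  # s
    dt: float = 0.001  # s

    def __post_init__(self) -> None:
        if self.direction not in ("extension", "flexion"):
            raise ValueError("direction must be 'extension' or 'flexion'")
        if self.dt <= 0.0 or self.duration <= 0.0 or self.n_steps < 1:
            raise ValueError("invalid protocol constants")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "extension" else -1.0


@dataclass
class SimulationResult:
    """Per-step trajectory of one branch plus its equilibrium summaries."""

    direction: str
    time_s: np.ndarray
    m_ext_nm: np.ndarray
    theta_deg: np.ndarray
    ligament_forces: dict[str, np.ndarray]
    contact_forces: np.ndarray  # n x 2
    plateau_theta_deg: np.ndarray
    final_state: PlanarState
    final_kinetic_energy: float
    final_residual: np.ndarray  # (Fx N, Fy N, tau Nm) at the last step

    @property
    def final_theta_deg(self) -> float:
        return float(self.theta_deg[-1])

    def max_ligament_force(self, name: str) -> float:
        return float(np.max(self.ligament_forces[name]))

    def max_contact_force(self) -> float:
        return float(np.max(self.contact_forces.sum(axis=1)))


def ligament_force(lig: Ligament, length: float) -> float:
    """Cable tension (N) at the given current length (mm).

    Quadratic toe up to strain 2*toe_strain, linear beyond, zero when slack;
    force and its slope are continuous at the branch change.
    """
    if not length > 0.0:
        raise ValueError(f"length must be positive, got {length}")
    eps = (length - lig.rest_length) / lig.rest_length
    return _cable_force(lig.stiffness, lig.toe_strain, eps)


def _cable_force(k: float, toe: float, eps: float) -> float:
    if eps <= 0.0:
        return 0.0
    if eps <= 2.0 * toe:
        return k * eps * eps / (4.0 * toe)
    return k * (eps - toe)


def _rot_cw(theta: float, ax: float, ay: float) -> tuple[float, float]:
    """Rotate a femur-frame vector clockwise by theta (flexion-positive)."""
    c, s = math.cos(theta), math.sin(theta)
    return c * ax + s * ay, -s * ax + c * ay


def _drot_cw(theta: float, ax: float, ay: float) -> tuple[float, float]:
    """d/dtheta of `_rot_cw` (kinematic Jacobian of an attached point)."""
    c, s = math.cos(theta), math.sin(theta)
    return -s * ax + c * ay, -c * ax - s * ay


def contact_state(
    model: KneeModel,
    state: PlanarState,
    curves: tuple[ForceIndentationCurve, ForceIndentationCurve],
) -> list[tuple[float, float, tuple[float, float], tuple[float, float]]]:
    """Per condylar pair: (indentation mm, force N, contact point mm, normal).

    Indentation is the penetration of the condyle circle past the plateau
    line; the force is the pair's curve evaluated there, acting along the
    plateau normal, zero at separation.
    """
    x_mm, y_mm = state.q[0] * 1e3, state.q[1] * 1e3
    th = state.q[2]
    nx, ny = model.plateau_normal
    px, py = model.plateau_point
    out = []
    for (cx, cy), curve in zip(model.condyle_centers, curves):
        ox, oy = _rot_cw(th, cx, cy)
        wx, wy = x_mm + ox, y_mm + oy
        dist = (wx - px) * nx + (wy - py) * ny
        delta = max(0.0, model.condyle_radius - dist)
        force = eval_curve(curve, delta) if delta > 0.0 else 0.0
        point = (wx - nx * dist, wy - ny * dist)
        out.append((delta, force, point, (nx, ny)))
    return out


def net_wrench(
    model: KneeModel,
    state: PlanarState,
    curves: tuple[ForceIndentationCurve, ForceIndentationCurve],
    applied_torque: float = 0.0,
) -> np.ndarray:
    """Generalized force (Fx N, Fy N, torque Nm) on the femur.

    Sums ligament tensions along their cable lines, condylar contact forces,
    linear viscous damping, and the applied generalized torque about the
    flexion coordinate.  Torques of attached forces are obtained through the
    kinematic Jacobian of the attachment point (virtual work), so the result
    is exactly the gradient form an independent statics check reproduces.
    """
    x, y = state.q[0], state.q[1]
    th = state.q[2]
    fx = fy = tau = 0.0
    for lig in model.ligaments:
        ax_m, ay_m = lig.femoral[0] * 1e-3, lig.femoral[1] * 1e-3
        ox, oy = _rot_cw(th, ax_m, ay_m)
        wx, wy = x + ox, y + oy
        tx_m, ty_m = lig.tibial[0] * 1e-3, lig.tibial[1] * 1e-3
        dx, dy = tx_m - wx, ty_m - wy
        length = math.hypot(dx, dy)
        f = _cable_force(
            lig.stiffness, lig.toe_strain, length / (lig.rest_length * 1e-3) - 1.0
        )
        if f > 0.0:
            ux, uy = dx / length, dy / length
            jx, jy = _drot_cw(th, ax_m, ay_m)
            fx += f * ux
            fy += f * uy
            tau += f * (ux * jx + uy * jy)
    nx, ny = model.plateau_normal
    for (cx, cy), curve in zip(model.condyle_centers, curves):
        cx_m, cy_m = cx * 1e-3, cy * 1e-3
        ox, oy = _rot_cw(th, cx_m, cy_m)
        dist_mm = ((x + ox) * 1e3 - model.plateau_point[0]) * nx + (
            (y + oy) * 1e3 - model.plateau_point[1]
        ) * ny
        delta = model.condyle_radius - dist_mm
        if delta > 0.0:
            f = eval_curve(curve, delta)
            jx, jy = _drot_cw(th, cx_m, cy_m)
            fx += f * nx
            fy += f * ny
            tau += f * (nx * jx + ny * jy)
    fx -= model.damping_translational * state.v[0]
    fy -= model.damping_translational * state.v[1]
    tau -= model.damping_rotational * state.v[2]
    tau += applied_torque
    return np.array([fx, fy, tau])


def step_semi_implicit(
    state: PlanarState, wrench: np.ndarray, dt: float, mass: float, inertia: float
) -> PlanarState:
    """One symplectic Euler step: velocity first, then position with it."""
    if not dt > 0.0:
        raise ValueError("dt must be positive")
    minv = np.array([1.0 / mass, 1.0 / mass, 1.0 / inertia])
    v = state.v + minv * np.asarray(wrench) * dt
    q = state.q + v * dt
    return PlanarState(q=q, v=v)


def _curve_evaluator(curve: ForceIndentationCurve):
    """Fast scalar piecewise-linear evaluator matching `eval_curve`."""
    ind = curve.indentations
    frc = curve.forces
    n = ind.size
    h = ind[1] - ind[0]
    uniform = bool(np.allclose(np.diff(ind), h))
    last = float(ind[-1])
    f_last = float(frc[-1])
    slope_last = float((frc[-1] - frc[-2]) / (ind[-1] - ind[-2]))
    ind_l = ind.tolist()
    frc_l = frc.tolist()

    def ev(d: float) -> float:
        if d <= 0.0:
            return 0.0
        if d >= last:
            return f_last + slope_last * (d - last)
        if uniform:
            i = int(d / h)
            if i >= n - 1:
                i = n - 2
        else:
            import bisect

            i = bisect.bisect_right(ind_l, d) - 1
        t = (d - ind_l[i]) / (ind_l[i + 1] - ind_l[i])
        return frc_l[i] + t * (frc_l[i + 1] - frc_l[i])

    return ev


_SPEED_GUARD = 5.0  # m/s
_OMEGA_GUARD = 50.0  # rad/s


def run_branch(
    model: KneeModel,
    curves: tuple[ForceIndentationCurve, ForceIndentationCurve],
    protocol: LoadProtocol,
) -> SimulationResult:
    """Simulate one branch of the stepped-moment protocol.

    The external moment rises by ``m_max / n_steps`` at the start of each of
    ``n_steps`` equal plateaus and is held constant in between; equilibrium
    knee angles are recorded at the end of each plateau.
    """
    n = int(round(protocol.duration / protocol.dt))
    plateau = n // protocol.n_steps
    dt = protocol.dt
    sign = protocol.sign
    mass, inertia = model.mass, model.inertia
    ct, cr = model.damping_translational, model.damping_rotational
    nx, ny = model.plateau_normal
    r_mm = model.condyle_radius
    px, py = model.plateau_point

    ligs = [
        (
            lig.femoral[0] * 1e-3,
            lig.femoral[1] * 1e-3,
            lig.tibial[0] * 1e-3,
            lig.tibial[1] * 1e-3,
            lig.stiffness,
            lig.rest_length * 1e-3,
            lig.toe_strain,
        )
        for lig in model.ligaments
    ]
    pairs = [
        ((cx * 1e-3, cy * 1e-3), _curve_evaluator(curve))
        for (cx, cy), curve in zip(model.condyle_centers, curves)
    ]

    x, y, th = PlanarState.from_pose(model.initial_pose).q
    vx = vy = om = 0.0

    time_s = np.arange(n) * dt
    m_ext_arr = np.empty(n)
    theta_arr = np.empty(n)
    lig_arr = np.empty((n, 4))
    con_arr = np.empty((n, 2))
    plateau_theta = []

    cos, sin, hypot = math.cos, math.sin, math.hypot
    for k in range(n):
        level = min(k // plateau + 1, protocol.n_steps)
        m_ext = sign * protocol.m_max * level / protocol.n_steps
        c, s = cos(th), sin(th)
        fx = fy = 0.0
        tau = -m_ext
        for i, (ax, ay, tx, ty, kk, l0, toe) in enumerate(ligs):
            ox = c * ax + s * ay
            oy = -s * ax + c * ay
            dx = tx - (x + ox)
            dy = ty - (y + oy)
            length = hypot(dx, dy)
            eps = length / l0 - 1.0
            if eps <= 0.0:
                lig_arr[k, i] = 0.0
                continue
            f = kk * eps * eps / (4.0 * toe) if eps <= 2.0 * toe else kk * (eps - toe)
            ux, uy = dx / length, dy / length
            jx = -s * ax + c * ay
            jy = -c * ax - s * ay
            fx += f * ux
            fy += f * uy
            tau += f * (ux * jx + uy * jy)
            lig_arr[k, i] = f
        for j, ((cx, cy), ev) in enumerate(pairs):
            ox = c * cx + s * cy
            oy = -s * cx + c * cy
            dist_mm = ((x + ox) * 1e3 - px) * nx + ((y + oy) * 1e3 - py) * ny
            delta = r_mm - dist_mm
            if delta > 0.0:
                f = ev(delta)
                jx = -s * cx + c * cy
                jy = -c * cx - s * cy
                fx += f * nx
                fy += f * ny
                tau += f * (nx * jx + ny * jy)
                con_arr[k, j] = f
            else:
                con_arr[k, j] = 0.0
        fx -= ct * vx
        fy -= ct * vy
        tau -= cr * om
        vx += fx / mass * dt
        vy += fy / mass * dt
        om += tau / inertia * dt
        x += vx * dt
        y += vy * dt
        th += om * dt
        m_ext_arr[k] = m_ext
        theta_arr[k] = math.degrees(th)
        if hypot(vx, vy) > _SPEED_GUARD or abs(om) > _OMEGA_GUARD:
            raise IntegrationError(
                f"{protocol.direction} branch diverged at step {k} "
                f"(t = {k * dt:.3f} s)"
            )
        if (k + 1) % plateau == 0 and len(plateau_theta) < protocol.n_steps:
            plateau_theta.append(math.degrees(th))

    final = PlanarState(q=np.array([x, y, th]), v=np.array([vx, vy, om]))
    ke = 0.5 * mass * (vx * vx + vy * vy) + 0.5 * inertia * om * om
    residual = net_wrench(model, final, curves, applied_torque=-m_ext_arr[-1])
    return SimulationResult(
        direction=protocol.direction,
        time_s=time_s,
        m_ext_nm=m_ext_arr,
        theta_deg=theta_arr,
        ligament_forces={
            name: lig_arr[:, i] for i, name in enumerate(LIGAMENT_NAMES)
        },
        contact_forces=con_arr,
        plateau_theta_deg=np.array(plateau_theta),
        final_state=final,
        final_kinetic_energy=float(ke),
        final_residual=residual,
    )


def angular_range(res_ext: SimulationResult, res_flex: SimulationResult) -> float:
    """Flexion-extension range (deg): final flexion minus final extension angle."""
    rng = res_flex.final_theta_deg - res_ext.final_theta_deg
    if rng < -1e-9:
        raise ValueError(
            "flexion branch ended more extended than the extension branch; "
            "are the branches swapped?"
        )
    return max(rng, 0.0)


def find_static_equilibrium(
    model: KneeModel,
    curves: tuple[ForceIndentationCurve, ForceIndentationCurve],
    guess_pose: tuple[float, float, float] | None = None,
    applied_torque: float = 0.0,
) -> tuple[float, float, float]:
    """Unloaded (or moment-loaded) static pose (x mm, y mm, theta deg).

    Solves the zero-velocity wrench balance with a damped quasi-Newton
    root finder starting from the model's initial pose.
    """
    pose0 = guess_pose if guess_pose is not None else model.initial_pose

    def residual(z: np.ndarray) -> np.ndarray:
        st = PlanarState(
            q=np.array([z[0] * 1e-3, z[1] * 1e-3, math.radians(z[2])]),
            v=np.zeros(3),
        )
        return net_wrench(model, st, curves, applied_torque=applied_torque)

    sol = root(residual, np.array(pose0), method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise RuntimeError(f"static equilibrium search failed: {sol.message}")
    return float(sol.x[0]), float(sol.x[1]), float(sol.x[2])
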