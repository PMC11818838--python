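"""Planar knee dynamics: cable law, contact, statics, integrator, branches."""

import math

import numpy as np
import pytest

from kneevar.contact import ForceIndentationCurve, eval_curve
from kneevar.knee_model import (
    KneeModel,
    Ligament,
    LoadProtocol,
    PlanarState,
    angular_range,
    contact_state,
    find_static_equilibrium,
    ligament_force,
    net_wrench,
    run_branch,
    step_semi_implicit,
)


# --- ligament cable law ----------------------------------------------------

def _cable(k=1000.0, l0=100.0):
    return Ligament("ACL", (0.0, 0.0), (0.0, -100.0), k, l0)


def test_cable_slack_at_and_below_rest_length():
    lig = _cable()
    assert ligament_force(lig, 100.0) == 0.0
    assert ligament_force(lig, 80.0) == 0.0


def test_cable_branches_and_continuity():
    lig = _cable()
    # toe formula at the branch point equals the linear formula
    assert ligament_force(lig, 106.0) == pytest.approx(30.0)
    assert 1000.0 * (0.06 - 0.03) == pytest.approx(30.0)
    assert ligament_force(lig, 110.0) == pytest.approx(70.0)
    # quadratic toe below the branch point
    assert ligament_force(lig, 103.0) == pytest.approx(1000.0 * 0.03**2 / 0.12)


def test_cable_slope_continuous_at_branch_change():
    lig = _cable()
    h = 1e-6
    below = (ligament_force(lig, 106.0) - ligament_force(lig, 106.0 - h)) / h
    above = (ligament_force(lig, 106.0 + h) - ligament_force(lig, 106.0)) / h
    assert below == pytest.approx(above, rel=1e-3)


def test_cable_rejects_nonpositive_length():
    with pytest.raises(ValueError):
        ligament_force(_cable(), 0.0)


# --- contact state ---------------------------------------------------------

def _linear_curve(slope=500.0):
    d = np.linspace(0.0, 1.0, 21)
    return ForceIndentationCurve(d, slope * d)


def _bare_model(theta0=0.0, y0=41.0):
    """Model with far-away slack ligaments; contact/ligament-free baseline."""
    slack = tuple(
        Ligament(name, (0.0, 0.0), (0.0, -500.0), 1000.0, 1000.0)
        for name in ("ACL", "PCL", "MCL", "LCL")
    )
    return KneeModel(
        ligaments=slack,
        condyle_centers=((0.0, 0.0), (0.0, 0.0)),
        condyle_radius=40.0,
        plateau_point=(0.0, 0.0),
        plateau_normal=(0.0, 1.0),
        mass=4.0,
        inertia=0.05,
        damping_translational=0.0,
        damping_rotational=0.0,
        initial_pose=(0.0, y0, theta0),
    )


def test_contact_state_separated_and_grazing():
    model = _bare_model(y0=41.0)
    curves = (_linear_curve(), _linear_curve())
    st = PlanarState.from_pose((0.0, 41.0, 0.0))
    assert all(f == 0.0 and d == 0.0 for d, f, _, _ in contact_state(model, st, curves))
    st = PlanarState.from_pose((0.0, 40.0, 0.0))
    assert all(f == 0.0 for _, f, _, _ in contact_state(model, st, curves))


def test_contact_state_passes_through_the_curve(mid_healthy_spec, healthy_curves):
    model = _bare_model()
    st = PlanarState.from_pose((0.0, 39.0, 0.0))  # 1.00 mm penetration
    states = contact_state(model, st, healthy_curves)
    for delta, force, point, normal in states:
        assert delta == pytest.approx(1.0, abs=1e-12)
        assert force == pytest.approx(eval_curve(healthy_curves[0], 1.0))
        assert point[1] == pytest.approx(0.0)
        assert normal == (0.0, 1.0)


# --- net wrench ------------------------------------------------------------

def test_free_femur_carries_only_the_applied_torque():
    model = _bare_model(y0=45.0)
    st = PlanarState.from_pose((0.0, 45.0, 10.0))
    w = net_wrench(model, st, (_linear_curve(), _linear_curve()), applied_torque=1.0)
    assert w == pytest.approx([0.0, 0.0, 1.0])


def test_single_vertical_ligament_statics():
    """A taut vertical cable on the reference axis pulls straight down."""
    ligs = (
        Ligament("ACL", (0.0, 0.0), (0.0, -100.0), 1000.0, 30.0),
        Ligament("PCL", (0.0, 0.0), (0.0, -500.0), 1000.0, 1000.0),
        Ligament("MCL", (0.0, 0.0), (0.0, -500.0), 1000.0, 1000.0),
        Ligament("LCL", (0.0, 0.0), (0.0, -500.0), 1000.0, 1000.0),
    )
    model = KneeModel(
        ligaments=ligs,
        condyle_centers=((0.0, 0.0), (0.0, 0.0)),
        condyle_radius=40.0,
        plateau_point=(0.0, 0.0),
        plateau_normal=(0.0, 1.0),
        mass=4.0,
        inertia=0.05,
        damping_translational=0.0,
        damping_rotational=0.0,
        initial_pose=(0.0, 100.0, 0.0),
    )
    st = PlanarState.from_pose((0.0, 100.0, 37.0))  # attachment on the axis
    tension = ligament_force(ligs[0], 200.0)
    w = net_wrench(model, st, (_linear_curve(), _linear_curve()))
    assert w[0] == pytest.approx(0.0, abs=1e-12)
    assert w[1] == pytest.approx(-tension)
    assert w[2] == pytest.approx(0.0, abs=1e-12)


def test_wrench_torque_matches_virtual_work_oracle(nominal_model, healthy_curves):
    """Q_theta equals sum F . dp/dtheta with the Jacobian from finite differences."""
    st = PlanarState(
        q=np.array([-0.004, 0.0394, math.radians(60.0)]), v=np.zeros(3)
    )
    w = net_wrench(nominal_model, st, healthy_curves)

    # independent statics: differentiate attachment kinematics numerically
    h = 1e-7
    tau = 0.0
    for lig in nominal_model.ligaments:
        def world(theta, a=lig.femoral):
            c, s = math.cos(theta), math.sin(theta)
            return np.array(
                [st.q[0] + (c * a[0] + s * a[1]) * 1e-3,
                 st.q[1] + (-s * a[0] + c * a[1]) * 1e-3]
            )
        p0 = world(st.q[2])
        t = np.array(lig.tibial) * 1e-3
        length = np.linalg.norm(t - p0)
        f = ligament_force(lig, length * 1e3)
        if f > 0.0:
            u = (t - p0) / length
            jac = (world(st.q[2] + h) - world(st.q[2] - h)) / (2 * h)
            tau += f * float(u @ jac)
    for (cx, cy), curve in zip(nominal_model.condyle_centers, healthy_curves):
        def centre(theta, a=(cx, cy)):
            c, s = math.cos(theta), math.sin(theta)
            return np.array(
                [st.q[0] + (c * a[0] + s * a[1]) * 1e-3,
                 st.q[1] + (-s * a[0] + c * a[1]) * 1e-3]
            )
        c0 = centre(st.q[2])
        delta = nominal_model.condyle_radius - c0[1] * 1e3
        if delta > 0:
            f = eval_curve(curve, delta)
            jac = (centre(st.q[2] + h) - centre(st.q[2] - h)) / (2 * h)
            tau += f * float(np.array([0.0, 1.0]) @ jac)
    assert w[2] == pytest.approx(tau, abs=1e-9)


# --- semi-implicit Euler ---------------------------------------------------

def test_step_keeps_quiescent_state():
    st = PlanarState(q=np.zeros(3), v=np.zeros(3))
    out = step_semi_implicit(st, np.zeros(3), 0.001, 4.0, 0.05)
    assert np.all(out.q == 0.0) and np.all(out.v == 0.0)


def test_step_constant_force_closed_form():
    """n steps under constant force: x = F/m dt^2 n(n+1)/2 exactly."""
    m, dt, F, n = 4.0, 0.001, np.array([2.0, 0.0, 0.0]), 250
    st = PlanarState(q=np.zeros(3), v=np.zeros(3))
    for _ in range(n):
        st = step_semi_implicit(st, F, dt, m, 0.05)
    assert st.q[0] == pytest.approx(F[0] / m * dt**2 * n * (n + 1) / 2, rel=1e-12)


def test_step_linear_spring_energy_bounded():
    """16 s of an undamped spring at dt = 1 ms stays bounded (symplectic)."""
    k, m, dt = 500.0, 4.0, 0.001
    st = PlanarState(q=np.array([0.01, 0.0, 0.0]), v=np.zeros(3))
    energies = []
    for i in range(16000):
        w = np.array([-k * st.q[0], 0.0, 0.0])
        st = step_semi_implicit(st, w, dt, m, 0.05)
        if i % 1000 == 0:
            energies.append(0.5 * m * st.v[0] ** 2 + 0.5 * k * st.q[0] ** 2)
    e0 = 0.5 * k * 0.01**2
    assert max(energies) < 1.1 * e0
    assert min(energies) > 0.5 * e0


def test_step_rejects_nonpositive_dt():
    st = PlanarState(q=np.zeros(3), v=np.zeros(3))
    with pytest.raises(ValueError):
        step_semi_implicit(st, np.zeros(3), 0.0, 4.0, 0.05)


# --- branch simulation on the nominal model -------------------------------

def test_unloaded_branch_stays_at_static_equilibrium(nominal_model, healthy_curves):
    protocol = LoadProtocol("extension", m_max=0.0, duration=4.0)
    res = run_branch(nominal_model, healthy_curves, protocol)
    eq = find_static_equilibrium(nominal_model, healthy_curves)
    assert abs(res.final_theta_deg - eq[2]) < 1e-3
    assert abs(res.final_theta_deg - nominal_model.initial_pose[2]) < 1e-3


def test_extension_branch_extends_the_knee(nominal_branches, nominal_model):
    ext, flex = nominal_branches
    assert ext.final_theta_deg < nominal_model.initial_pose[2]
    assert flex.final_theta_deg > nominal_model.initial_pose[2]
    assert len(ext.plateau_theta_deg) == 5
    # plateau angles move monotonically toward extension
    assert np.all(np.diff(ext.plateau_theta_deg) < 0.0)


def test_branches_settle_to_equilibrium(nominal_branches):
    for res in nominal_branches:
        assert res.final_kinetic_energy < 1e-6
        assert np.max(np.abs(res.final_residual)) < 1e-3


def test_ligament_and_contact_forces_are_unilateral(nominal_branches):
    for res in nominal_branches:
        for forces in res.ligament_forces.values():
            assert np.all(forces >= 0.0)
        assert np.all(res.contact_forces >= 0.0)


def test_acl_is_silent_in_flexion(nominal_branches):
    _, flex = nominal_branches
    assert flex.max_ligament_force("ACL") == 0.0


def test_angular_range_nominal(nominal_branches):
    ext, flex = nominal_branches
    assert 63.0 <= angular_range(ext, flex) <= 85.0


def test_oa_tissue_gives_larger_range(nominal_branches, nominal_branches_oa):
    ext_h, flex_h = nominal_branches
    ext_o, flex_o = nominal_branches_oa
    assert angular_range(ext_o, flex_o) > angular_range(ext_h, flex_h)


def test_moment_protocol_steps_five_times(nominal_branches):
    ext, _ = nominal_branches
    levels = np.unique(np.abs(ext.m_ext_nm))
    assert levels.size == 5
    assert levels[-1] == pytest.approx(3.5)
    assert np.all(np.diff(np.abs(ext.m_ext_nm)) >= 0.0)


def test_swapped_branches_are_rejected(nominal_branches):
    ext, flex = nominal_branches
    with pytest.raises(ValueError):
        angular_range(flex, ext)
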