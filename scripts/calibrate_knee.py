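"""Calibration of the synthetic nominal knee.

Re-derives the frozen constants in ``kneevar.synthetic_knee`` from the
architectural parameters below and verifies the behavioural anchors.  Run
from the repository root:

    python scripts/calibrate_knee.py [--verify]

Design of the synthetic sagittal model (x posterior, y up, tibia fixed,
plateau at y = 0, condyle circles of radius 40 mm centred at the femur
origin):

* The femoral attachment of each cable is given in polar form
  (radius, angle) about the condyle centre in the full-extension frame;
  rotating the femur by the flexion angle theta sweeps the attachment
  clockwise, so a cable's lever arm about the centre varies with theta and
  vanishes where the attachment direction aligns with the cable ("isometric
  point").  The arm placements below implement the intended mechanics:

  - ACL: anterior-inferior attachment whose ~25 mm extension lever is
    nearly stationary over the extension stop; engages ACL_MARGIN degrees
    below the neutral angle, so it is slack at neutral and throughout
    flexion.
  - PCL: isometric near the extension end (its anterior-glide check-rein
    tension there transfers no torque noise into the ACL) with a strong
    flexion lever; engages PCL_MARGIN degrees above neutral.
  - MCL: isometric near full extension, an extension-restoring lever in
    deep flexion; pretensioned, the main source of contact preload.
  - LCL: short, near-isometric, pretensioned; stabilises the anterior
    glide of the femur.

* The second condylar pair ("posterior facet") is centred 4.5 mm superior
  to the first in the femur frame, so it engages only in deep flexion and
  feeds cartilage-dependent torque into the flexion moment balance.

Rest lengths are anchored to the *equilibrated* pose: the model is first
equilibrated with provisional values, then the ACL/PCL slack lengths are
recomputed at the equilibrium pose offset by their engagement margins and
the equilibrium is re-solved until the pose is self-consistent.  The
resulting pose and rest lengths are the constants frozen in
``synthetic_knee.py``.
"""

from __future__ import annotations

import argparse
import math

from kneevar.contact import eval_curve
from kneevar.knee_model import (
    KneeModel,
    Ligament,
    LoadProtocol,
    angular_range,
    find_static_equilibrium,
    run_branch,
)
from kneevar.synthetic_knee import (
    CONDYLE_RADIUS_MM,
    nominal_curves,
)

# --- architectural parameters (mm, deg, N) --------------------------------
THETA0_TARGET = 55.0  # neutral flexion angle the anchors aim at
DELTA0_GUESS = 0.37  # initial contact preload indentation, mm

ACL = dict(radius=28.0, angle=-30.0, tibial=(-30.0, -2.0), k=4000.0)
PCL = dict(radius=20.0, angle=-15.0, tibial=(18.0, -5.0), k=9000.0)
MCL = dict(radius=12.0, angle=-75.0, tibial=(-38.0, -55.0), k=8000.0, pretension=115.0)
LCL = dict(radius=8.0, angle=-9.0, tibial=(8.0, -45.0), k=800.0, pretension=60.0)
ACL_MARGIN = 32.0  # deg below neutral at which the ACL engages
PCL_MARGIN = 23.0  # deg above neutral at which the PCL engages
FACET_OFFSET = (0.0, 4.5)  # second condylar centre, femur frame

MASS = 4.0  # kg
INERTIA = 0.05  # kg m^2
DAMPING_TRANS = 3000.0  # N s/m
DAMPING_ROT = 0.25  # N m s/rad
TOE = 0.03


def polar(radius: float, angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return radius * math.cos(a), radius * math.sin(a)


def length_at(pose, attachment, tibial) -> float:
    """Cable length (mm) at a pose (x mm, y mm, theta deg)."""
    x, y, th_deg = pose
    th = math.radians(th_deg)
    c, s = math.cos(th), math.sin(th)
    wx = x + c * attachment[0] + s * attachment[1]
    wy = y - s * attachment[0] + c * attachment[1]
    return math.hypot(tibial[0] - wx, tibial[1] - wy)


def strain_at_tension(k: float, f: float) -> float:
    """Invert the quadratic-toe/linear cable law for the strain at tension f."""
    eps = f / k + TOE
    return eps if eps > 2.0 * TOE else math.sqrt(4.0 * TOE * f / k)


def build_nominal() -> KneeModel:
    acl_f, pcl_f = polar(ACL["radius"], ACL["angle"]), polar(PCL["radius"], PCL["angle"])
    mcl_f, lcl_f = polar(MCL["radius"], MCL["angle"]), polar(LCL["radius"], LCL["angle"])
    y0 = CONDYLE_RADIUS_MM - DELTA0_GUESS
    pose = (0.0, y0, THETA0_TARGET)
    rest = {
        "ACL": length_at((0.0, y0, THETA0_TARGET - ACL_MARGIN), acl_f, ACL["tibial"]),
        "PCL": length_at((0.0, y0, THETA0_TARGET + PCL_MARGIN), pcl_f, PCL["tibial"]),
        "MCL": length_at(pose, mcl_f, MCL["tibial"])
        / (1.0 + strain_at_tension(MCL["k"], MCL["pretension"])),
        "LCL": length_at(pose, lcl_f, LCL["tibial"])
        / (1.0 + strain_at_tension(LCL["k"], LCL["pretension"])),
    }

    def make(pose):
        return KneeModel(
            ligaments=(
                Ligament("ACL", acl_f, ACL["tibial"], ACL["k"], rest["ACL"]),
                Ligament("PCL", pcl_f, PCL["tibial"], PCL["k"], rest["PCL"]),
                Ligament("MCL", mcl_f, MCL["tibial"], MCL["k"], rest["MCL"]),
                Ligament("LCL", lcl_f, LCL["tibial"], LCL["k"], rest["LCL"]),
            ),
            condyle_centers=((0.0, 0.0), FACET_OFFSET),
            condyle_radius=CONDYLE_RADIUS_MM,
            plateau_point=(0.0, 0.0),
            plateau_normal=(0.0, 1.0),
            mass=MASS,
            inertia=INERTIA,
            damping_translational=DAMPING_TRANS,
            damping_rotational=DAMPING_ROT,
            initial_pose=pose,
        )

    curves = nominal_curves("healthy")
    eq = find_static_equilibrium(make(pose), curves)
    # anchor the cruciate slack lengths to the equilibrated pose, repeat
    # until pose and rest lengths are mutually consistent
    for _ in range(4):
        rest["ACL"] = length_at((eq[0], eq[1], eq[2] - ACL_MARGIN), acl_f, ACL["tibial"])
        rest["PCL"] = length_at((eq[0], eq[1], eq[2] + PCL_MARGIN), pcl_f, PCL["tibial"])
        eq = find_static_equilibrium(make(eq), curves)
    return make(eq)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--verify", action="store_true",
                    help="also run both branches and print the anchors")
    args = ap.parse_args()

    model = build_nominal()
    print("# frozen constants for kneevar.synthetic_knee")
    print("initial_pose = (%.12f, %.12f, %.12f)" % model.initial_pose)
    for lig in model.ligaments:
        print(
            "%s: femoral=(%.12f, %.12f) tibial=%s k=%g rest_length=%.12f"
            % (lig.name, *lig.femoral, lig.tibial, lig.stiffness, lig.rest_length)
        )
    if args.verify:
        curves = nominal_curves("healthy")
        ext = run_branch(model, curves, LoadProtocol("extension"))
        flex = run_branch(model, curves, LoadProtocol("flexion"))
        print("\n# anchors")
        print("neutral theta0        : %7.2f deg (target ~55)" % model.initial_pose[2])
        print("angular range         : %7.2f deg (anchor ~74)" % angular_range(ext, flex))
        print("extension end         : %7.2f deg" % ext.final_theta_deg)
        print("flexion end           : %7.2f deg" % flex.final_theta_deg)
        print("ACL max (flexion)     : %7.3f N (must be 0)" % flex.max_ligament_force("ACL"))
        print("contact preload       : %7.1f N" %
              sum(eval_curve(c, model.condyle_radius - model.initial_pose[1])
                  for c in curves))
        print("settle KE ext/flex    : %.1e / %.1e J"
              % (ext.final_kinetic_energy, flex.final_kinetic_energy))


if __name__ == "__main__":
    main()
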