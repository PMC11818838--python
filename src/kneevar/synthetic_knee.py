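"""Synthetic nominal knee: the stand-in for the reference planar model.

The multibody stage of this package follows a published planar tibiofemoral
architecture (four ligament cables, two condylar sphere-plane pairs, a
neutral pose near 55 degrees of flexion and roughly 74 degrees of motion
under +/- 3.5 Nm), but the reference model's numerical parameters are not
publicly available.  This module therefore carries a calibrated synthetic
parameter set whose *printed anchors* are respected exactly (40 mm condyle
radius, 2.3 / 2.1 mm cartilage, 55-degree neutral pose) and whose emergent
behaviour reproduces the documented anchors:

* neutral equilibrium near 55 deg flexion,
* flexion-extension range of roughly 74 deg under +/- 3.5 Nm,
* an ACL that is slack throughout the flexion branch,
* every moment plateau settling within its 3.2 s hold.

The geometry was produced by the calibration procedure in
``scripts/calibrate_knee.py`` (see that script and docs/methods.md for the
design rationale); the resulting constants are frozen here so that
`default_model()` is deterministic and needs no solver at import time.

Anatomy of the synthetic sagittal model (x posterior, y up, mm):

* Both condylar circles (radius 40) are centred at the femur origin; the
  second ("posterior facet") centre sits 4.5 mm superior, so that pair
  engages only in deep flexion and feeds cartilage-dependent torque into
  the flexion stop.
* ACL: anterior-inferior femoral attachment with a flat ~25 mm extension
  lever; the extension stop.  Engages ~32 deg below neutral.
* PCL: near-isometric at the extension end (its check-rein tension there
  transfers no torque), strong flexion lever; engages ~23 deg above
  neutral.
* MCL: isometric near full extension, extension-restoring lever in deep
  flexion; pretensioned, the main contact preload.
* LCL: short near-isometric pretensioned cable; lateral/posterior
  stabiliser of the anterior glide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .contact import (
    CartilageLayer,
    ContactPairSpec,
    ForceIndentationCurve,
    compute_curve,
)
from .knee_model import KneeModel, Ligament
from .materials import YeohParams
from .sampling import LIGAMENTS, LigamentPerturbation, MaterialRanges

__all__ = [
    "NominalKneeSpec",
    "RunDescriptor",
    "default_model",
    "nominal_spec",
    "nominal_contact_spec",
    "nominal_curves",
    "apply_perturbation",
    "build_study",
]

# geometry printed in the source study
CONDYLE_RADIUS_MM = 40.0  # sphere radius of the condylar contact pair
FEMORAL_THICKNESS_MM = 2.3  # femoral cartilage layer
TIBIAL_THICKNESS_MM = 2.1  # tibial cartilage layer

# frozen output of scripts/calibrate_knee.py (synthetic, see module docstring)
_INITIAL_POSE = (-5.572981379374, 39.480720940568, 56.015966362680)
_FACET_OFFSET_MM = (0.0, 4.5)
_LIGAMENTS = (
    # name, femoral (mm), tibial (mm), stiffness (N), rest length (mm)
    ("ACL", (24.248711305964, -14.0), (-30.0, -2.0), 4000.0, 45.004418357208),
    ("PCL", (19.318516525781, -5.176380902050), (18.0, -5.0), 9000.0, 35.005667463546),
    ("MCL", (3.105828541230, -11.591109915469), (-38.0, -55.0), 8000.0, 87.032051003714),
    ("LCL", (7.901506724761, -1.251475720322), (8.0, -45.0), 800.0, 70.198986820743),
)
_MASS_KG = 4.0
_INERTIA_KGM2 = 0.05
_DAMPING_TRANS = 3000.0  # N s / m
_DAMPING_ROT = 0.25  # N m s / rad

_PROVENANCE = {
    "condyle_radius": "printed (40 mm sphere radius)",
    "femoral_thickness": "printed (2.3 mm femoral cartilage)",
    "tibial_thickness": "printed (2.1 mm tibial cartilage)",
    "bone_modulus": "printed (17200 MPa, documentation only; backing is rigid)",
    "initial_pose": "synthetic, calibrated to a ~55 deg neutral equilibrium",
    "ligaments": "synthetic, calibrated (scripts/calibrate_knee.py)",
    "facet_offset": "synthetic, posterior facet engaging in deep flexion",
    "mass_inertia_damping": "synthetic, chosen so every plateau settles",
    "load_protocol": "printed (+/- 3.5 Nm, 5 steps, 16.0 s, dt 0.001 s)",
}


@dataclass(frozen=True)
class NominalKneeSpec:
    """The nominal model plus a provenance note for every parameter group."""

    model: KneeModel
    provenance: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class RunDescriptor:
    """One (ligament variant, tissue group, material sample) simulation."""

    run_id: str
    variant_id: int
    group: str
    sample_id: int


def default_model() -> KneeModel:
    """Deterministic nominal planar knee; identical on every call."""
    ligs = tuple(
        Ligament(name, fem, tib, stiffness=k, rest_length=l0)
        for name, fem, tib, k, l0 in _LIGAMENTS
    )
    return KneeModel(
        ligaments=ligs,
        condyle_centers=((0.0, 0.0), _FACET_OFFSET_MM),
        condyle_radius=CONDYLE_RADIUS_MM,
        plateau_point=(0.0, 0.0),
        plateau_normal=(0.0, 1.0),
        mass=_MASS_KG,
        inertia=_INERTIA_KGM2,
        damping_translational=_DAMPING_TRANS,
        damping_rotational=_DAMPING_ROT,
        initial_pose=_INITIAL_POSE,
    )


def nominal_spec() -> NominalKneeSpec:
    return NominalKneeSpec(model=default_model(), provenance=dict(_PROVENANCE))


def nominal_contact_spec(group: str = "healthy") -> ContactPairSpec:
    """Condylar pair with mid-range Yeoh constants of the given group."""
    ranges = MaterialRanges().group(group)
    mid = {k: 0.5 * (lo + hi) for k, (lo, hi) in (
        (name, getattr(ranges, name)) for name in (
            "femoral_c10", "femoral_c20", "tibial_c10", "tibial_c20"))}
    return ContactPairSpec(
        sphere_radius=CONDYLE_RADIUS_MM,
        femoral=CartilageLayer(
            FEMORAL_THICKNESS_MM,
            YeohParams(mid["femoral_c10"], mid["femoral_c20"]),
        ),
        tibial=CartilageLayer(
            TIBIAL_THICKNESS_MM,
            YeohParams(mid["tibial_c10"], mid["tibial_c20"]),
        ),
    )


_CURVE_CACHE: dict[str, tuple[ForceIndentationCurve, ForceIndentationCurve]] = {}


def nominal_curves(group: str = "healthy") -> tuple[ForceIndentationCurve, ForceIndentationCurve]:
    """Force-indentation curves of the mid-range tissue, one per condylar pair."""
    if group not in _CURVE_CACHE:
        curve = compute_curve(nominal_contact_spec(group))
        _CURVE_CACHE[group] = (curve, curve)
    return _CURVE_CACHE[group]


def apply_perturbation(model: KneeModel, pert: LigamentPerturbation) -> KneeModel:
    """Ligament variant: shift attachments, scale stiffnesses; rest unchanged.

    Offsets are applied to the attachment coordinates in each bone's local
    frame; the original model is not modified.
    """
    new_ligs = []
    for i, lig in enumerate(model.ligaments):
        new_ligs.append(
            Ligament(
                name=lig.name,
                femoral=(
                    lig.femoral[0] + pert.offsets[i, 0, 0],
                    lig.femoral[1] + pert.offsets[i, 0, 1],
                ),
                tibial=(
                    lig.tibial[0] + pert.offsets[i, 1, 0],
                    lig.tibial[1] + pert.offsets[i, 1, 1],
                ),
                stiffness=lig.stiffness * pert.stiffness_factors[i],
                rest_length=lig.rest_length,
                toe_strain=lig.toe_strain,
            )
        )
    return KneeModel(
        ligaments=tuple(new_ligs),
        condyle_centers=model.condyle_centers,
        condyle_radius=model.condyle_radius,
        plateau_point=model.plateau_point,
        plateau_normal=model.plateau_normal,
        mass=model.mass,
        inertia=model.inertia,
        damping_translational=model.damping_translational,
        damping_rotational=model.damping_rotational,
        initial_pose=model.initial_pose,
    )


def build_study(
    n_variants, n_samples, groups: tuple[str, ...] = ("healthy", "oa")
) -> list[RunDescriptor]:
    """Full run matrix: every variant x group x material sample.

    ``n_variants`` and ``n_samples`` may be counts or the sequences of
    variant models / per-group curves themselves.  With the study defaults
    (32 variants, 64 samples, two groups) this is the 4096-run matrix;
    scaled-down studies use the same id scheme so runs are stable and
    comparable across study sizes.
    """
    if not isinstance(n_variants, int):
        n_variants = len(n_variants)
    if not isinstance(n_samples, int):
        n_samples = len(n_samples)
    if n_variants < 1 or n_samples < 1 or not groups:
        raise ValueError("study must contain at least one variant, sample and group")
    out = []
    for v in range(n_variants):
        for g in groups:
            for s in range(n_samples):
                out.append(
                    RunDescriptor(
                        run_id=f"v{v:02d}-{g}-s{s:02d}",
                        variant_id=v,
                        group=g,
                        sample_id=s,
                    )
                )
    return out
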