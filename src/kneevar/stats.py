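"""Summary statistics of the variability study.

Dispersion is reported as the coefficient of variation CV = 100 * SD / mean
(sample SD, n-1 denominator) and, for angular-displacement ranges, as the
relative range

    RDiff = 100 * (range_max - range_min) / range_mean

computed over the material samples of one ligament-system variant and
tissue group.  Both statistics are scale-free: multiplying every input by a
common factor leaves them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .knee_model import SimulationResult, angular_range

__all__ = [
    "GroupStats",
    "CompressionSummary",
    "VariantSummary",
    "coefficient_of_variation",
    "rdiff",
    "summarize_compression",
    "summarize_variant",
]

#: branch whose peak force enters the ligament CV (the ACL is inactive in
#: flexion, so its maximum is taken on the extension branch)
LIGAMENT_CV_BRANCH = {"ACL": "extension", "PCL": "flexion", "MCL": "flexion", "LCL": "flexion"}


@dataclass(frozen=True)
class GroupStats:
    """Mean/SD/CV/min/max of one batch of forces or ranges."""

    mean: float
    sd: float
    cv: float
    min: float
    max: float


@dataclass(frozen=True)
class CompressionSummary:
    """Contact-force statistics at full indentation, per group and pooled."""

    healthy: GroupStats
    oa: GroupStats
    combined: GroupStats


@dataclass(frozen=True)
class VariantSummary:
    """One ligament-variant row of the flexion-extension study tables."""

    variant_id: int
    rdiff_h: float
    cv_h: float
    rdiff_oa: float
    cv_oa: float
    rdiff_c: float
    cv_c: float
    range_c: float  # max pooled angular range, deg
    ligament_cv_h: dict[str, float]
    ligament_cv_oa: dict[str, float]

    def to_row(self) -> dict[str, float]:
        row = {
            "ID": self.variant_id,
            "RDiff_H_pct": self.rdiff_h,
            "CV_H_pct": self.cv_h,
            "RDiff_OA_pct": self.rdiff_oa,
            "CV_OA_pct": self.cv_oa,
            "RDiff_C_pct": self.rdiff_c,
            "CV_C_pct": self.cv_c,
            "Range_C_deg": self.range_c,
        }
        for name in ("ACL", "PCL", "LCL", "MCL"):
            row[f"CV_{name}_H_pct"] = self.ligament_cv_h[name]
            row[f"CV_{name}_OA_pct"] = self.ligament_cv_oa[name]
        return row


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample SD / mean (undefined for zero mean)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("CV of an empty batch is undefined")
    mean = v.mean()
    if mean == 0.0:
        raise ZeroDivisionError("CV is undefined for zero mean")
    if v.size == 1:
        return 0.0
    return float(100.0 * v.std(ddof=1) / mean)


def rdiff(ranges) -> float:
    """Relative change of angular displacement, 100 * (max - min) / mean."""
    v = np.asarray(ranges, dtype=float)
    if v.size == 0:
        raise ValueError("RDiff of an empty batch is undefined")
    mean = v.mean()
    if mean <= 0.0:
        raise ValueError(f"RDiff requires a positive mean range, got {mean}")
    return float(100.0 * (v.max() - v.min()) / mean)


def _group_stats(values) -> GroupStats:
    v = np.asarray(values, dtype=float)
    return GroupStats(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        cv=coefficient_of_variation(v),
        min=float(v.min()),
        max=float(v.max()),
    )


def summarize_compression(healthy_forces, oa_forces) -> CompressionSummary:
    """Per-group and pooled statistics of the forces at full indentation."""
    h = np.asarray(healthy_forces, dtype=float)
    o = np.asarray(oa_forces, dtype=float)
    if h.shape != o.shape:
        raise ValueError(
            f"groups must be paired batches of equal size, got {h.shape} vs {o.shape}"
        )
    return CompressionSummary(
        healthy=_group_stats(h),
        oa=_group_stats(o),
        combined=_group_stats(np.concatenate([h, o])),
    )


def summarize_variant(
    variant_id: int,
    healthy: list[tuple[SimulationResult, SimulationResult]],
    oa: list[tuple[SimulationResult, SimulationResult]],
) -> VariantSummary:
    """Table row for one ligament variant from paired (extension, flexion) runs.

    ``healthy`` and ``oa`` hold one (extension branch, flexion branch) result
    pair per material sample, the two groups paired through the shared Sobol
    design.  Ligament CVs are computed from each run's maximum
    flexion-branch force for the PCL, LCL and MCL and the maximum
    extension-branch force for the ACL.
    """
    if not healthy or len(healthy) != len(oa):
        raise ValueError("variant requires equal, non-empty healthy and OA batches")
    for batch in (healthy, oa):
        for pair in batch:
            ext, flex = pair
            if ext.direction != "extension" or flex.direction != "flexion":
                raise ValueError(
                    "each sample must provide (extension, flexion) branches"
                )
    ranges_h = [angular_range(ext, flex) for ext, flex in healthy]
    ranges_oa = [angular_range(ext, flex) for ext, flex in oa]
    pooled = ranges_h + ranges_oa

    def lig_cvs(batch):
        out = {}
        for name, branch in LIGAMENT_CV_BRANCH.items():
            idx = 0 if branch == "extension" else 1
            out[name] = coefficient_of_variation(
                [pair[idx].max_ligament_force(name) for pair in batch]
            )
        return out

    return VariantSummary(
        variant_id=variant_id,
        rdiff_h=rdiff(ranges_h),
        cv_h=coefficient_of_variation(ranges_h),
        rdiff_oa=rdiff(ranges_oa),
        cv_oa=coefficient_of_variation(ranges_oa),
        rdiff_c=rdiff(pooled),
        cv_c=coefficient_of_variation(pooled),
        range_c=float(max(pooled)),
        ligament_cv_h=lig_cvs(healthy),
        ligament_cv_oa=lig_cvs(oa),
    )
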