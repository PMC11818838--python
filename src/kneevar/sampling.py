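"""Sobol designs for the two sampling stages of the variability study.

Stage 1 samples the four Yeoh constants of the condylar cartilage (femoral
C10/C20, tibial C10/C20) over mean +/- 1 SD ranges for healthy and
osteoarthritic tissue; one shared 64-point unit design is scaled to both
groups so samples are paired across groups.  Stage 2 samples the ligament
system: 16 attachment-coordinate offsets (+/- 1.0 mm) and 4 stiffness
multipliers (+/- 10%) from a 20-dimensional 32-point design.

Points are unscrambled base-2 Sobol (scipy.stats.qmc) with the origin
included, so every design is bit-identical between runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .materials import YeohParams

__all__ = [
    "LIGAMENTS",
    "STAGE1_COLUMNS",
    "SobolDesign",
    "GroupRanges",
    "MaterialRanges",
    "LigamentPerturbation",
    "sobol_unit",
    "scale_stage1",
    "scale_stage2",
]

LIGAMENTS = ("ACL", "PCL", "MCL", "LCL")
STAGE1_COLUMNS = ("femoral_c10", "femoral_c20", "tibial_c10", "tibial_c20")


@dataclass(frozen=True)
class SobolDesign:
    """An n x dim matrix of unit-hypercube sample points."""

    dim: int
    n: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.shape != (self.n, self.dim):
            raise ValueError(f"samples must be {self.n}x{self.dim}, got {s.shape}")
        if np.any(s < 0.0) or np.any(s >= 1.0):
            raise ValueError("sample entries must lie in [0, 1)")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class GroupRanges:
    """Per-constant (min, max) bounds in MPa, stage-1 column order."""

    femoral_c10: tuple[float, float]
    femoral_c20: tuple[float, float]
    tibial_c10: tuple[float, float]
    tibial_c20: tuple[float, float]

    def __post_init__(self) -> None:
        for name in STAGE1_COLUMNS:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")

    def bounds(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STAGE1_COLUMNS])


@dataclass(frozen=True)
class MaterialRanges:
    """Healthy and OA variation ranges of the four Yeoh constants.

    Defaults are the published mean +/- 1 SD experimental ranges for human
    condylar cartilage (healthy and osteoarthritis-affected donors).
    """

    healthy: GroupRanges = field(
        default_factory=lambda: GroupRanges(
            femoral_c10=(0.6, 2.2),
            femoral_c20=(0.0, 7.3),
            tibial_c10=(1.2, 2.8),
            tibial_c20=(1.8, 7.2),
        )
    )
    oa: GroupRanges = field(
        default_factory=lambda: GroupRanges(
            femoral_c10=(0.4, 2.0),
            femoral_c20=(0.3, 4.1),
            tibial_c10=(0.3, 1.9),
            tibial_c20=(1.8, 3.6),
        )
    )

    def group(self, name: str) -> GroupRanges:
        if name not in ("healthy", "oa"):
            raise KeyError(f"unknown group {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class LigamentPerturbation:
    """One stage-2 sample of the ligament system.

    ``offsets[i, j, k]`` is the mm shift of ligament ``LIGAMENTS[i]``,
    attachment ``j`` (0 = femoral, 1 = tibial), coordinate ``k`` (0 = x,
    1 = y); ``stiffness_factors[i]`` multiplies the ligament's stiffness.
    """

    offsets: np.ndarray
    stiffness_factors: np.ndarray

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=float)
        mul = np.asarray(self.stiffness_factors, dtype=float)
        if off.shape != (4, 2, 2):
            raise ValueError(f"offsets must be 4x2x2, got {off.shape}")
        if mul.shape != (4,):
            raise ValueError(f"stiffness_factors must have shape (4,), got {mul.shape}")
        if np.any(np.abs(off) > 1.0 + 1e-12):
            raise ValueError("attachment offsets must lie in [-1, 1] mm")
        if np.any(mul < 0.9 - 1e-12) or np.any(mul > 1.1 + 1e-12):
            raise ValueError("stiffness multipliers must lie in [0.9, 1.1]")
        object.__setattr__(self, "offsets", off)
        object.__setattr__(self, "stiffness_factors", mul)


def sobol_unit(dim: int, n: int) -> SobolDesign:
    """Deterministic unscrambled Sobol points (origin included)."""
    if dim < 1 or n < 1:
        raise ValueError("dim and n must both be at least 1")
    with warnings.catch_warnings():
        # scipy warns when n is not a power of two; scaled-down test designs
        # deliberately use such n, and balance is not required there.
        warnings.simplefilter("ignore", UserWarning)
        samples = qmc.Sobol(d=dim, scramble=False).random(n)
    return SobolDesign(dim=dim, n=n, samples=samples)


def scale_stage1(
    design: SobolDesign, ranges: MaterialRanges, group: str
) -> list[tuple[YeohParams, YeohParams]]:
    """Scale a 4-d unit design to (femoral, tibial) Yeoh parameter pairs."""
    if design.dim != 4:
        raise ValueError(f"stage-1 design must be 4-dimensional, got {design.dim}")
    bounds = ranges.group(group).bounds()
    scaled = bounds[:, 0] + design.samples * (bounds[:, 1] - bounds[:, 0])
    return [
        (YeohParams(c10=row[0], c20=row[1]), YeohParams(c10=row[2], c20=row[3]))
        for row in scaled
    ]


def scale_stage2(design: SobolDesign) -> list[LigamentPerturbation]:
    """Scale a 20-d unit design to ligament perturbations.

    Columns 0-15 map to attachment offsets in [-1, +1] mm in fixed order
    (ACL, PCL, MCL, LCL) x (femoral, tibial) x (x, y); columns 16-19 map to
    stiffness multipliers in [0.9, 1.1] in ligament order.
    """
    if design.dim != 20:
        raise ValueError(f"stage-2 design must be 20-dimensional, got {design.dim}")
    out = []
    for row in design.samples:
        offsets = (-1.0 + 2.0 * row[:16]).reshape(4, 2, 2)
        factors = 0.9 + 0.2 * row[16:20]
        out.append(LigamentPerturbation(offsets=offsets, stiffness_factors=factors))
    return out
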