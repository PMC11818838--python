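"""End-to-end orchestration of the two-stage variability study.

Stage 1 (`run_compression_study`): one shared 4-d Sobol design scaled to
the healthy and OA material ranges; the layered contact model is solved for
every sample and the force-indentation curves plus the compression
statistics at full indentation are written.

Stage 2 (`run_flexion_extension_study`): a 20-d Sobol design perturbs the
ligament system into variants; every variant is simulated in flexion and
extension against every per-sample cartilage curve of both groups and
summarised into one table row per variant (plus an AVG row).

Everything is deterministic: identical configurations yield byte-identical
CSV outputs.  A small command-line front end exposes the two studies as
``kneevar compression`` and ``kneevar flexion-extension``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from .contact import (
    CartilageLayer,
    ContactPairSpec,
    ForceIndentationCurve,
    compute_curve,
    write_curve_csv,
)
from .knee_model import LoadProtocol, run_branch
from .sampling import (
    STAGE1_COLUMNS,
    MaterialRanges,
    scale_stage1,
    scale_stage2,
    sobol_unit,
)
from .stats import (
    CompressionSummary,
    VariantSummary,
    summarize_compression,
    summarize_variant,
)
from .synthetic_knee import (
    FEMORAL_THICKNESS_MM,
    TIBIAL_THICKNESS_MM,
    CONDYLE_RADIUS_MM,
    apply_perturbation,
    build_study,
    default_model,
)

__all__ = ["StudyConfig", "run_compression_study", "run_flexion_extension_study", "cli"]

log = logging.getLogger("kneevar")

GROUPS = ("healthy", "oa")


@dataclass(frozen=True)
class StudyConfig:
    """Study constants; the defaults are the published protocol."""

    stage1_n: int = 64  # material samples per group
    stage2_n: int = 32  # ligament-system variants
    delta_max: float = 1.00  # mm
    n_delta_steps: int = 20
    m_max: float = 3.5  # Nm
    n_moment_steps: int = 5
    duration: float = 16.0  # s
    dt: float = 0.001  # s
    groups: tuple[str, ...] = GROUPS
    output_dir: str | None = None
    # scale-down knobs for quick runs; None means the full study size
    n_samples_override: int | None = None
    n_variants_override: int | None = None

    @property
    def n_samples(self) -> int:
        return self.n_samples_override or self.stage1_n

    @property
    def n_variants(self) -> int:
        return self.n_variants_override or self.stage2_n

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "groups" in data:
            data["groups"] = tuple(data["groups"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["groups"] = list(data["groups"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _pair_spec(fem, tib) -> ContactPairSpec:
    return ContactPairSpec(
        sphere_radius=CONDYLE_RADIUS_MM,
        femoral=CartilageLayer(FEMORAL_THICKNESS_MM, fem),
        tibial=CartilageLayer(TIBIAL_THICKNESS_MM, tib),
    )


def run_compression_study(config: StudyConfig = StudyConfig()):
    """Solve the stage-1 contact batch and summarise forces at delta_max.

    Returns ``(summary, curves_by_group, params_by_group)``; if
    ``config.output_dir`` is set, writes one curve CSV per sample, a JSON
    manifest (sample index -> group -> Yeoh constants) and the summary.
    """
    n = config.n_samples
    design = sobol_unit(4, n)
    ranges = MaterialRanges()
    curves: dict[str, list[ForceIndentationCurve]] = {}
    params: dict[str, list] = {}
    forces: dict[str, np.ndarray] = {}
    for group in config.groups:
        pairs = scale_stage1(design, ranges, group)
        params[group] = pairs
        group_curves = []
        for i, (fem, tib) in enumerate(pairs):
            curve = compute_curve(_pair_spec(fem, tib), config.delta_max, config.n_delta_steps)
            group_curves.append(curve)
            log.info("compression %s sample %d: F(delta_max) = %.2f N",
                     group, i, curve.forces[-1])
        curves[group] = group_curves
        forces[group] = np.array([c.forces[-1] for c in group_curves])
    summary = summarize_compression(forces["healthy"], forces["oa"])
    if config.output_dir:
        _write_compression_outputs(config, summary, curves, params)
    return summary, curves, params


def _write_compression_outputs(config, summary, curves, params) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for group, group_curves in curves.items():
        for i, curve in enumerate(group_curves):
            name = f"curve_{group}_{i:03d}.csv"
            write_curve_csv(curve, out / name)
            fem, tib = params[group][i]
            manifest[name] = {
                "sample": i,
                "group": group,
                "femoral_c10_mpa": fem.c10,
                "femoral_c20_mpa": fem.c20,
                "tibial_c10_mpa": tib.c10,
                "tibial_c20_mpa": tib.c20,
            }
    (out / "curves_manifest.json").write_text(
        json.dumps(
            {"column_order": list(STAGE1_COLUMNS), "curves": manifest}, indent=2
        )
    )
    (out / "compression_summary.json").write_text(
        json.dumps(
            {
                g: dataclasses.asdict(getattr(summary, g))
                for g in ("healthy", "oa", "combined")
            },
            indent=2,
        )
    )


def run_flexion_extension_study(
    config: StudyConfig = StudyConfig(), curves: dict[str, list] | None = None
) -> pd.DataFrame:
    """Simulate every (variant, group, sample) run and build the table.

    Returns a DataFrame with one row per ligament variant plus an AVG row.
    Curves may be passed in from a previous compression study; otherwise
    they are computed on the fly.
    """
    if curves is None:
        _, curves, _ = run_compression_study(
            dataclasses.replace(config, output_dir=None)
        )
    n_var = config.n_variants
    design2 = sobol_unit(20, config.stage2_n)
    perturbations = scale_stage2(design2)[:n_var]
    nominal = default_model()
    descriptors = build_study(n_var, config.n_samples, tuple(config.groups))
    log.info("flexion-extension study: %d runs", len(descriptors))
    protocols = {
        "extension": LoadProtocol(
            "extension", config.m_max, config.n_moment_steps, config.duration, config.dt
        ),
        "flexion": LoadProtocol(
            "flexion", config.m_max, config.n_moment_steps, config.duration, config.dt
        ),
    }
    rows = []
    summaries: list[VariantSummary] = []
    for v, pert in enumerate(perturbations):
        model = apply_perturbation(nominal, pert)
        outcomes = {g: [] for g in config.groups}
        for g in config.groups:
            for s in range(config.n_samples):
                pair_curves = (curves[g][s], curves[g][s])
                ext = run_branch(model, pair_curves, protocols["extension"])
                flex = run_branch(model, pair_curves, protocols["flexion"])
                log.info(
                    "run v%02d-%s-s%02d: theta %.2f..%.2f deg, residual %.1e",
                    v, g, s, ext.final_theta_deg, flex.final_theta_deg,
                    float(np.max(np.abs(ext.final_residual))),
                )
                outcomes[g].append((ext, flex))
        summary = summarize_variant(v + 1, outcomes["healthy"], outcomes["oa"])
        summaries.append(summary)
        rows.append(summary.to_row())
    table = pd.DataFrame(rows)
    avg = table.drop(columns=["ID"]).mean()
    avg["ID"] = "AVG"
    table = pd.concat([table, avg.to_frame().T], ignore_index=True)
    table = table[rows[0].keys() if rows else table.columns]
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "flexion_extension_variants.csv", index=False)
    return table


def _common_options(fn):
    fn = click.option("--config", "config_path", type=click.Path(exists=True),
                      default=None, help="YAML study configuration")(fn)
    fn = click.option("--out", "output_dir", type=click.Path(), default=None,
                      help="output directory")(fn)
    fn = click.option("--samples", type=int, default=None,
                      help="scale-down: material samples per group")(fn)
    fn = click.option("--variants", type=int, default=None,
                      help="scale-down: ligament variants")(fn)
    fn = click.option("-v", "--verbose", is_flag=True, help="per-run logging")(fn)
    return fn


def _build_config(config_path, output_dir, samples, variants, verbose) -> StudyConfig:
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                        format="%(message)s")
    cfg = StudyConfig.from_yaml(config_path) if config_path else StudyConfig()
    return dataclasses.replace(
        cfg,
        output_dir=output_dir or cfg.output_dir,
        n_samples_override=samples or cfg.n_samples_override,
        n_variants_override=variants or cfg.n_variants_override,
    )


@click.group()
def cli():
    """Yeoh-cartilage variability study in a planar hybrid knee model."""


@cli.command()
@_common_options
def compression(config_path, output_dir, samples, variants, verbose):
    """Stage 1: solve the contact batch and print the force statistics."""
    cfg = _build_config(config_path, output_dir, samples, variants, verbose)
    summary, _, _ = run_compression_study(cfg)
    for name in ("healthy", "oa", "combined"):
        g = getattr(summary, name)
        click.echo(
            f"{name:>8}: mean {g.mean:7.1f} N  SD {g.sd:6.1f} N  "
            f"CV {g.cv:5.1f} %  min {g.min:6.1f}  max {g.max:6.1f}"
        )


@cli.command("flexion-extension")
@_common_options
def flexion_extension(config_path, output_dir, samples, variants, verbose):
    """Stage 2: simulate the hybrid knee variants and print the table."""
    cfg = _build_config(config_path, output_dir, samples, variants, verbose)
    table = run_flexion_extension_study(cfg)
    click.echo(table.to_string(index=False))
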