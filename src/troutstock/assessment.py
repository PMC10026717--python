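"""One-command end-to-end assessment: data -> allometry -> growth -> mortality
-> reference points -> harvest policies -> density.

The report aggregates every stage's Results object plus provenance (input
hash, seed, package version) so a machine-format render is reproducible
byte for byte from the same inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import LengthWeightResults, fit_length_weight, impute_missing_mass
from .data import (
    Dataset,
    Gear,
    Purpose,
    deduplicate_recaptures,
    read_fish_table,
    select_subset,
)
from .density import GroupComparison, compare_groups, density_table
from .growth import (
    GrowthFamily,
    GrowthModel,
    GrowthResults,
    ModelComparison,
    amgr,
    compare_models_aicc,
    sensitivity_refit,
)
from .harvest import HarvestPolicy, compare_policies
from .mortality import (
    ChapmanRobsonResults,
    LimbMode,
    MortalityPartition,
    build_catch_curve,
    chapman_robson,
    natural_mortality_tmax,
    partition_mortality,
    select_descending_limb,
)
from .refpoints import ReferencePoints, compute_reference_points
from .simulate import SyntheticConfig, simulate_population

__all__ = ["AssessmentConfig", "AssessmentReport", "run_full_assessment", "render_report", "StageError"]

logger = logging.getLogger("troutstock")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class AssessmentConfig:
    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    policies: tuple[HarvestPolicy, ...] = (
        HarvestPolicy.minimum_length(35.0),
        HarvestPolicy.minimum_length(40.0),
    )
    t_max: float = 11.0
    limb_mode: LimbMode = LimbMode.EXCLUDE_PEAK
    max_limb_class: int | None = None
    sensitivity_drop: int = 3
    transects: pd.DataFrame | None = None  # transect_id, tract, year, length_m
    catch_gear: Gear | None = Gear.ANGLING  # lengths evaluated against policies

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("configure exactly one of input_path / synthetic")


@dataclass
class AssessmentReport:
    allometry: LengthWeightResults
    growth_comparison: ModelComparison
    growth: GrowthResults  # the AICc-selected fit
    amgr: float | None
    sensitivity: dict | None
    catch_curve: pd.DataFrame
    chapman_robson: ChapmanRobsonResults
    mortality: MortalityPartition
    reference_points: ReferencePoints
    harvest: pd.DataFrame | None
    density: pd.DataFrame | None
    density_comparison: GroupComparison | None
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _load(cfg: AssessmentConfig) -> tuple[Dataset, str]:
    if cfg.synthetic is not None:
        ds = simulate_population(cfg.synthetic)
        source = f"synthetic seed={cfg.synthetic.seed} n={cfg.synthetic.n}"
        digest = hashlib.sha256(repr(cfg.synthetic).encode()).hexdigest()[:16]
    else:
        path = Path(cfg.input_path)
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        ds = read_fish_table(path, provenance=str(path))
        source = str(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    return ds, f"{source} sha256:{digest}"


def run_full_assessment(cfg: AssessmentConfig) -> AssessmentReport:
    """Run every stage in order; stage failures carry the stage label."""
    caught: list[str] = []

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                out = fn(*args, **kwargs)
            for w in wlist:
                caught.append(f"{name}: {w.message}")
                logger.warning("%s: %s", name, w.message)
            return out
        except Exception as exc:  # noqa: BLE001 - stage label added for the user
            raise StageError(name, exc) from exc

    ds, provenance_src = stage("input", _load, cfg)
    ds = stage("dedup", deduplicate_recaptures, ds)

    lw = stage("allometry", fit_length_weight, ds)
    ds = stage("imputation", impute_missing_mass, ds, lw)

    def fit_all():
        models = {
            fam: GrowthModel(ds, fam)
            for fam in GrowthFamily
        }
        fits = {fam: m.fit() for fam, m in models.items()}
        comparison = compare_models_aicc(list(fits.values()))
        return models, fits, comparison

    models, fits, comparison = stage("growth", fit_all)
    best = comparison.best
    growth_fit = fits[best]
    growth_amgr = amgr(growth_fit) if best is GrowthFamily.GOMPERTZ else None

    sensitivity = None
    if cfg.sensitivity_drop > 0:
        refit, rel_change, ok = stage(
            "sensitivity", sensitivity_refit, models[best], growth_fit, cfg.sensitivity_drop
        )
        sensitivity = {
            "dropped": cfg.sensitivity_drop,
            "TL_inf": refit.TL_inf,
            "relative_change": rel_change,
            "within_10pct": ok,
        }

    curve = stage("catch_curve", build_catch_curve, ds)
    limb = stage(
        "descending_limb", select_descending_limb, curve, cfg.limb_mode, cfg.max_limb_class
    )
    cr = stage("chapman_robson", chapman_robson, limb)
    M = stage("natural_mortality", natural_mortality_tmax, cfg.t_max)
    partition = stage("mortality_partition", partition_mortality, cr.Z, M)

    rp = stage("reference_points", compute_reference_points, growth_fit.TL_inf)

    harvest = None
    frame = ds.frame
    catch = (
        frame[frame["gear"] == cfg.catch_gear.value] if cfg.catch_gear else frame
    )
    if cfg.policies and len(catch):
        harvest = stage(
            "harvest",
            compare_policies,
            catch["TL_cm"].to_numpy(float),
            list(cfg.policies),
            rp,
        )

    dens = dens_cmp = None
    if cfg.transects is not None:
        dens = stage("density", density_table, ds, cfg.transects)
        by_tract = {
            t: g["numerical_density"].to_numpy() for t, g in dens.groupby("tract")
        }
        if len(by_tract) >= 2:
            dens_cmp = stage("density_comparison", compare_groups, by_tract)

    return AssessmentReport(
        allometry=lw,
        growth_comparison=comparison,
        growth=growth_fit,
        amgr=growth_amgr,
        sensitivity=sensitivity,
        catch_curve=curve.to_frame(),
        chapman_robson=cr,
        mortality=partition,
        reference_points=rp,
        harvest=harvest,
        density=dens,
        density_comparison=dens_cmp,
        warnings=caught,
        provenance={"input": provenance_src, "version": __version__},
    )


def report_to_dict(report: AssessmentReport) -> dict:
    """Full-precision machine representation of a report."""
    d = {
        "provenance": report.provenance,
        "allometry": report.allometry.to_dict(),
        "growth": {
            "family": report.growth.family.value,
            "params": dict(zip(report.growth.param_names, report.growth.params)),
            "se": dict(zip(report.growth.param_names, report.growth.se)),
            "ci": {n: list(c) for n, c in zip(report.growth.param_names, report.growth.ci)},
            "rss": report.growth.rss,
            "n": report.growth.n,
            "aicc": report.growth.aicc,
            "converged": report.growth.converged,
        },
        "growth_comparison": report.growth_comparison.table.reset_index()
        .rename(columns={"index": "family"})
        .to_dict(orient="records"),
        "amgr": report.amgr,
        "sensitivity": report.sensitivity,
        "catch_curve": report.catch_curve.to_dict(orient="records"),
        "mortality": {
            "S_hat": report.chapman_robson.S_hat,
            "Z": report.chapman_robson.Z,
            "se_Z": report.chapman_robson.se_Z,
            "ci_Z": list(report.chapman_robson.ci_Z),
            "n": report.chapman_robson.n,
            "T": report.chapman_robson.T,
            "A_Z": report.mortality.A_Z,
            "M": report.mortality.M,
            "A_M": report.mortality.A_M,
            "F": report.mortality.F,
            "A_F": report.mortality.A_F,
            "E": report.mortality.E,
            "F_floored": report.mortality.F_floored,
        },
        "reference_points": {
            "TL_inf": report.reference_points.TL_inf,
            "TL_m": report.reference_points.TL_m,
            "TL_m_pi": list(report.reference_points.TL_m_pi),
            "TL_opt": report.reference_points.TL_opt,
            "TL_opt_pi": list(report.reference_points.TL_opt_pi),
            "slot": list(report.reference_points.slot),
            "megaspawner_threshold": report.reference_points.megaspawner_threshold,
        },
        "harvest": None
        if report.harvest is None
        else report.harvest.reset_index().to_dict(orient="records"),
        "density": None
        if report.density is None
        else report.density.to_dict(orient="records"),
        "warnings": report.warnings,
    }
    return d


def render_report(report: AssessmentReport, fmt: str = "text") -> str:
    """Serialize a report: 'text' (3-dp human), 'json' / 'delimited' (machine)."""
    if fmt == "json":
        return json.dumps(report_to_dict(report), indent=2, sort_keys=True)
    if fmt == "delimited":
        d = report_to_dict(report)
        lines = ["section\tkey\tvalue"]

        def emit(section, obj, prefix=""):
            if isinstance(obj, dict):
                for k, v in obj.items():
                    emit(section, v, f"{prefix}{k}." if isinstance(v, (dict, list)) else f"{prefix}{k}")
            elif isinstance(obj, list):
                for i, v in enumerate(obj):
                    emit(section, v, f"{prefix}{i}." if isinstance(v, (dict, list)) else f"{prefix}{i}")
            else:
                lines.append(f"{section}\t{prefix}\t{obj}")

        for section in ("allometry", "growth", "mortality", "reference_points"):
            emit(section, d[section])
        return "\n".join(lines) + "\n"
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    parts = [
        f"troutstock assessment v{report.provenance.get('version', '?')}",
        f"input: {report.provenance.get('input', '?')}",
        "",
        report.allometry.summary(),
        "",
        report.growth_comparison.summary(),
        "",
        report.growth.summary(),
    ]
    if report.amgr is not None:
        parts.append(f"  AMGR  {report.amgr:.3f} cm yr^-1")
    if report.sensitivity:
        s = report.sensitivity
        parts.append(
            f"  sensitivity (drop {s['dropped']} largest): TL_inf {s['TL_inf']:.1f} cm, "
            f"change {100 * s['relative_change']:.1f}% "
            f"({'within' if s['within_10pct'] else 'exceeds'} 10%)"
        )
    parts += ["", report.chapman_robson.summary(), "", report.mortality.summary(), "", report.reference_points.summary()]
    if report.harvest is not None:
        parts += ["", "Harvest-policy evaluation:", report.harvest.to_string(float_format=lambda v: f"{v:.3f}")]
    if report.density is not None:
        parts += ["", "Per-transect densities:", report.density.to_string(float_format=lambda v: f"{v:.3f}")]
        if report.density_comparison is not None:
            parts += ["", report.density_comparison.summary()]
    if report.warnings:
        parts += ["", "Warnings:"] + [f"  - {w}" for w in report.warnings]
    return "\n".join(parts) + "\n"
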