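"""Pipeline configuration and full-inventory report assembly.

Ties the stages together: spike-in qPCR and/or blot quantification give
total hTR per cell; the IP depletion table gives assembled RNP monomers;
elution stoichiometry gives total hTERT; the direct assay gives specific
activity; the dGTP titration gives Km/Vmax. Stages whose inputs are absent
are skipped with an explicit log entry, and downstream dependents are
skipped too. Every constant and formula substitution is logged at INFO so
the mass-balance arithmetic is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assay as assay_mod
from . import blot as blot_mod
from . import inventory as inventory_mod
from . import kinetics as kinetics_mod
from . import qpcr as qpcr_mod
from .exceptions import ValidationError

log = logging.getLogger("telquant")


@dataclass
class PipelineConfig:
    """Paths and constants for a full-inventory run.

    All inputs are optional; present inputs decide which stages run.
    """

    qpcr_wells: Path | None = None
    qpcr_design: Path | None = None
    qpcr_target: str = "hTR_1"
    qpcr_reference: str = "GAPDH"
    blot_lanes: Path | None = None
    inventory_table: Path | None = None
    assay_gel: Path | None = None
    kinetics_table: Path | None = None
    seed: int = 0
    output_dir: Path = Path(".")
    flags: dict = field(default_factory=dict)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or not raw:
            raise ValidationError(
                "empty pipeline config; expected a YAML mapping with any of the keys: "
                "qpcr_wells, qpcr_design, qpcr_target, qpcr_reference, blot_lanes, "
                "inventory_table, assay_gel, kinetics_table, seed, output_dir"
            )
        path_keys = {
            "qpcr_wells",
            "qpcr_design",
            "blot_lanes",
            "inventory_table",
            "assay_gel",
            "kinetics_table",
        }
        kwargs: dict = {}
        for key, value in raw.items():
            if key in path_keys:
                p = Path(value)
                if not p.exists():
                    raise ValidationError(f"configured input {key} does not exist: {p}")
                kwargs[key] = p
            elif key == "output_dir":
                kwargs[key] = Path(value)
            elif key in ("qpcr_target", "qpcr_reference", "seed", "flags"):
                kwargs[key] = value
            else:
                raise ValidationError(f"unknown config key {key!r}")
        return PipelineConfig(**kwargs)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonable, allow_nan=True))


def lanes_from_csv(path: str | Path) -> list[blot_mod.LaneMeasurement]:
    """Read a blot lane table (lane_id,target,role,signal,...) into lane objects."""
    df = pd.read_csv(path)
    lanes = []
    for _, row in df.iterrows():
        def opt(col):
            return float(row[col]) if col in row and pd.notna(row[col]) else None

        lanes.append(
            blot_mod.LaneMeasurement(
                lane_id=str(row["lane_id"]),
                target=str(row["target"]),
                signal=float(row["signal"]),
                role=str(row["role"]),
                std_molecules=opt("std_molecules"),
                cells_loaded=opt("cells_loaded"),
                elution_volume_ul=opt("elution_volume_ul"),
            )
        )
    return lanes


def run_inventory(config: PipelineConfig) -> dict:
    """Execute all stages the configured inputs allow; return the report."""
    report: dict = {"seed": config.seed, "stages": {}, "skipped": []}

    htr_per_cell: float | None = None
    if config.qpcr_wells and config.qpcr_design:
        wells = pd.read_csv(config.qpcr_wells)
        design = pd.read_csv(config.qpcr_design)
        fit = qpcr_mod.estimate_copies_from_tables(
            wells, design, config.qpcr_target, config.qpcr_reference
        )
        log.info(
            "spike-in qPCR: slope %.3e per molecule -> %.1f copies/reaction, %.1f copies/cell",
            fit.slope_per_molecule,
            fit.endogenous_per_reaction,
            fit.endogenous_per_cell,
        )
        htr_per_cell = fit.endogenous_per_cell
        report["stages"]["spikein_qpcr"] = {
            "slope_per_molecule": fit.slope_per_molecule,
            "r_squared": fit.r_squared,
            "endogenous_per_reaction": fit.endogenous_per_reaction,
            "endogenous_per_cell": fit.endogenous_per_cell,
            "n_points": fit.n_points,
            "warnings": fit.warnings,
        }
    else:
        report["skipped"].append("spikein_qpcr: wells/design inputs missing")

    if config.blot_lanes:
        lanes = lanes_from_csv(config.blot_lanes)
        standards = [l for l in lanes if l.role == "standard"]
        samples = [l for l in lanes if l.role == "sample"]
        curve = blot_mod.fit_standard_curve(standards)
        stage: dict = {
            "slope_signal_per_molecule": curve.slope_signal_per_molecule,
            "r_squared": curve.r_squared,
            "samples": {},
        }
        per_cell_vals = []
        for lane in samples:
            est = blot_mod.quantify_band(lane.signal, curve)
            entry = {"molecules": est.molecules, "flags": est.flags}
            if lane.cells_loaded:
                entry["molecules_per_cell"] = blot_mod.copies_per_cell(
                    est.molecules, lane.cells_loaded
                )
                per_cell_vals.append(entry["molecules_per_cell"])
            if lane.elution_volume_ul:
                entry["molecules_per_ul"] = blot_mod.molecules_per_ul(
                    est.molecules, lane.elution_volume_ul
                )
            stage["samples"][lane.lane_id] = entry
        if per_cell_vals:
            mean, sd = inventory_mod.replicate_summary(per_cell_vals)
            stage["molecules_per_cell_mean"] = mean
            stage["molecules_per_cell_sd"] = sd
            if htr_per_cell is None:
                htr_per_cell = mean
        report["stages"]["blot_quant"] = stage
    else:
        report["skipped"].append("blot_quant: lane table missing")

    if config.inventory_table:
        table = pd.read_csv(config.inventory_table)
        if "n_hTR_per_cell" not in table.columns and htr_per_cell is not None:
            table["n_hTR_per_cell"] = htr_per_cell
            log.info("inventory: using upstream hTR estimate %.1f copies/cell", htr_per_cell)
        report["stages"]["ip_inventory"] = inventory_mod.summarize_experiments(table)
    else:
        report["skipped"].append("ip_inventory: depletion table missing")

    if config.assay_gel:
        gels = pd.read_csv(config.assay_gel)
        recipe = assay_mod.AssayRecipe()
        pool = assay_mod.dgtp_pool(recipe)
        log.info(
            "direct assay: dGTP pool %.2f uM, SA %.3e dpm/pmol",
            pool.total_conc_um,
            pool.specific_activity_dpm_per_pmol,
        )
        activities = []
        stage = {
            "pool": {
                "total_conc_um": pool.total_conc_um,
                "hot_fraction": pool.hot_fraction,
                "specific_activity_dpm_per_pmol": pool.specific_activity_dpm_per_pmol,
            },
            "assays": {},
        }
        for _, row in gels.iterrows():
            gel = assay_mod.GelQuantification(
                products_signal_au=float(row["products_signal"]),
                lc_signal_au=float(row["lc_signal"]),
                lc_cpm=float(row["lc_cpm"]),
                lc_band_fraction=float(row.get("lc_band_fraction", 0.9)),
                n_telomerase_molecules=float(row["n_telomerase"]),
                fraction_of_elution_assayed=float(row.get("fraction_assayed", 1.0)),
            )
            sa = assay_mod.assay_specific_activity(
                gel, pool, float(row.get("duration_min", recipe.duration_min))
            )
            stage["assays"][str(row["assay_id"])] = {"nt_per_enzyme_min": sa}
            activities.append(sa)
        if activities:
            mean, sd = inventory_mod.replicate_summary(activities)
            stage["specific_activity_mean"] = mean
            stage["specific_activity_sd"] = sd
        report["stages"]["direct_assay"] = stage
    else:
        report["skipped"].append("direct_assay: gel table missing")

    if config.kinetics_table:
        table = pd.read_csv(config.kinetics_table)
        report["stages"]["kinetics"] = kinetics_mod.fit_replicates(table)
    else:
        report["skipped"].append("kinetics: velocity table missing")

    for skipped in report["skipped"]:
        log.info("stage skipped - %s", skipped)
    return report
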