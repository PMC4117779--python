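"""IP mass-balance estimators for assembled telomerase RNP and total hTERT.

The central trick: immunoprecipitating hTERT depletes *assembled* RNP (all
telomerase activity) and the assembled share of hTR, but free hTR stays in
the flow-through. With flow-through/input depletion ratios r_act (activity)
and r_hTR, the fraction of hTR that is assembled equals
(1 - r_hTR)/(1 - r_act), so

    N_RNP = N_hTR x (1 - r_hTR) / (1 - r_act)

Both depletions scale with the same pull-down efficiency, which therefore
cancels: the estimator does not depend on how complete the IP was. Total
hTERT then follows from elution stoichiometry — hTR in the elution counts
RNP monomers (hTR elutes only in complex), while hTERT in the elution counts
all antibody-bound hTERT — so

    N_hTERT = N_RNP x (hTERT per μl elution) / (hTR per μl elution)

assuming equal antibody affinity for assembled and free hTERT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import EstimationError, ValidationError


@dataclass(frozen=True)
class DepletionRatios:
    """Flow-through/input ratios for telomerase activity and hTR."""

    r_act: float
    r_htr: float

    def __post_init__(self) -> None:
        for name, v in (("r_act", self.r_act), ("r_htr", self.r_htr)):
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")

    @staticmethod
    def from_measurements(
        activity_input: float,
        activity_flow_through: float,
        htr_input: float,
        htr_flow_through: float,
    ) -> "DepletionRatios":
        """Build ratios from paired input/flow-through measurements.

        Both members of each pair must be in the same units and normalized
        to the same cell-equivalents.
        """
        if activity_input <= 0 or htr_input <= 0:
            raise ValidationError("input measurements must be > 0")
        return DepletionRatios(
            r_act=min(activity_flow_through / activity_input, 1.0),
            r_htr=min(htr_flow_through / htr_input, 1.0),
        )


@dataclass(frozen=True)
class ElutionStoichiometry:
    """hTR and hTERT concentrations in the IP elution (molecules/μl)."""

    htr_per_ul: float
    htert_per_ul: float

    def __post_init__(self) -> None:
        if self.htr_per_ul <= 0 or self.htert_per_ul <= 0:
            raise ValidationError("elution concentrations must be > 0")


@dataclass
class MonomerEstimate:
    """Assembled-RNP estimate with its implied assembled fraction and flags."""

    monomers_per_cell: float
    assembled_fraction: float
    flags: list[str] = field(default_factory=list)


@dataclass
class CellInventory:
    """Per-cell component counts with derived free pools."""

    htr_per_cell: float
    htert_per_cell: float
    rnp_monomers_per_cell: float
    rnp_dimers_per_cell: float
    free_htr: float
    free_htert: float
    flags: list[str] = field(default_factory=list)


def assembled_monomers_per_cell(n_htr: float, ratios: DepletionRatios) -> MonomerEstimate:
    """Assembled telomerase monomers per cell from IP depletion ratios.

    ``n_htr x (1 - r_hTR)/(1 - r_act)``. Requires r_act < 1 (some activity
    must have been depleted). When r_hTR < r_act the implied assembled
    fraction exceeds 1 — physically impossible but reachable under noise —
    and the estimate is returned with a warning flag rather than an error.
    """
    if n_htr <= 0:
        raise ValidationError(f"n_htr must be > 0, got {n_htr}")
    if ratios.r_act >= 1:
        raise EstimationError("r_act = 1: no activity depleted, estimator undefined")
    frac = (1.0 - ratios.r_htr) / (1.0 - ratios.r_act)
    flags = []
    if frac > 1:
        flags.append(
            f"implied assembled fraction {frac:.3f} > 1 (r_hTR < r_act); "
            "likely measurement noise"
        )
    return MonomerEstimate(
        monomers_per_cell=n_htr * frac, assembled_fraction=frac, flags=flags
    )


def tert_per_cell(n_rnp: float, elution: ElutionStoichiometry) -> float:
    """Total hTERT per cell from RNP count and elution stoichiometry."""
    if n_rnp < 0:
        raise ValidationError(f"n_rnp must be >= 0, got {n_rnp}")
    return n_rnp * elution.htert_per_ul / elution.htr_per_ul


def replicate_summary(values: Iterable[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1) over replicate estimates; SD is NaN for n=1."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("empty replicate list")
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    return float(arr.mean()), sd


def build_inventory(n_htr: float, n_htert: float, n_rnp: float) -> CellInventory:
    """Assemble the per-cell inventory and derived free pools.

    Free pools are totals minus assembled monomers, floored at zero with a
    flag when an estimate implies more RNP than subunit (never an error:
    these are noisy measurements, and downstream consumers need the flags).
    """
    for name, v in (("n_htr", n_htr), ("n_htert", n_htert), ("n_rnp", n_rnp)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    flags = []
    if n_rnp > n_htr:
        flags.append(f"rnp ({n_rnp:.0f}) exceeds total hTR ({n_htr:.0f})")
    if n_rnp > n_htert:
        flags.append(f"rnp ({n_rnp:.0f}) exceeds total hTERT ({n_htert:.0f})")
    return CellInventory(
        htr_per_cell=n_htr,
        htert_per_cell=n_htert,
        rnp_monomers_per_cell=n_rnp,
        rnp_dimers_per_cell=n_rnp / 2.0,
        free_htr=max(n_htr - n_rnp, 0.0),
        free_htert=max(n_htert - n_rnp, 0.0),
        flags=flags,
    )


def summarize_experiments(table: pd.DataFrame) -> dict:
    """Per-cell-line inventory report from a replicate measurement table.

    Expected columns: ``experiment_id, cell_line, replicate, n_hTR_per_cell,
    r_act, r_hTR`` and optionally ``hTR_per_ul_elution, hTERT_per_ul_elution``.
    Returns per-replicate estimates plus mean ± SD per cell line.
    """
    required = {"cell_line", "replicate", "n_hTR_per_cell", "r_act", "r_hTR"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"inventory table missing columns: {sorted(missing)}")
    report: dict = {}
    for cell_line, grp in table.groupby("cell_line", sort=False):
        reps = []
        for _, row in grp.iterrows():
            ratios = DepletionRatios(r_act=float(row["r_act"]), r_htr=float(row["r_hTR"]))
            est = assembled_monomers_per_cell(float(row["n_hTR_per_cell"]), ratios)
            rep = {
                "replicate": int(row["replicate"]),
                "monomers_per_cell": est.monomers_per_cell,
                "assembled_fraction": est.assembled_fraction,
                "flags": est.flags,
            }
            if (
                "hTR_per_ul_elution" in row
                and "hTERT_per_ul_elution" in row
                and pd.notna(row["hTR_per_ul_elution"])
                and pd.notna(row["hTERT_per_ul_elution"])
            ):
                elution = ElutionStoichiometry(
                    htr_per_ul=float(row["hTR_per_ul_elution"]),
                    htert_per_ul=float(row["hTERT_per_ul_elution"]),
                )
                rep["htert_per_cell"] = tert_per_cell(est.monomers_per_cell, elution)
            reps.append(rep)
        mono_mean, mono_sd = replicate_summary([r["monomers_per_cell"] for r in reps])
        entry = {
            "replicates": reps,
            "monomers_per_cell_mean": mono_mean,
            "monomers_per_cell_sd": mono_sd,
        }
        tert_vals = [r["htert_per_cell"] for r in reps if "htert_per_cell" in r]
        if tert_vals:
            tert_mean, tert_sd = replicate_summary(tert_vals)
            entry["htert_per_cell_mean"] = tert_mean
            entry["htert_per_cell_sd"] = tert_sd
            htr_mean = float(grp["n_hTR_per_cell"].mean())
            inv = build_inventory(htr_mean, tert_mean, mono_mean)
            entry["inventory"] = {
                "htr_per_cell": inv.htr_per_cell,
                "htert_per_cell": inv.htert_per_cell,
                "rnp_monomers_per_cell": inv.rnp_monomers_per_cell,
                "rnp_dimers_per_cell": inv.rnp_dimers_per_cell,
                "free_htr": inv.free_htr,
                "free_htert": inv.free_htert,
                "flags": inv.flags,
            }
        report[str(cell_line)] = entry
    return report
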