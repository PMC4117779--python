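"""Absolute RNA copy number by spike-in titration RT-qPCR.

A known number of in-vitro-transcribed standard molecules is titrated into
total RNA from a counted number of cells *before* reverse transcription, so
standard and endogenous target share the RT and PCR environment (including
any non-specific primer annealing that would distort a conventional external
standard curve). For each spiked sample the reference-normalized quantity is
compared to a matched unspiked sample:

    R_i = Q_spiked_i / Q_unspiked_i - 1

which estimates the standard:endogenous molar ratio. Plotting R_i against
the number of standard molecules added (S_i) gives a line through the
origin, R = m*S; the endogenous amount per reaction is where R = 1, i.e.
1/m, and dividing by cells per reaction gives copies per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EstimationError, ValidationError

#: Cq replicate range above which a well group is flagged (cycles).
CQ_REPLICATE_RANGE_FLAG = 0.5


@dataclass(frozen=True)
class QpcrWell:
    """One qPCR well: a sample/target pair with its quantification cycle."""

    sample_id: str
    target: str
    cq: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.cq <= 45):
            raise ValidationError(f"Cq must be in [0, 45], got {self.cq}")
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")


@dataclass(frozen=True)
class TitrationPoint:
    """One spike-in level: standard added and the paired relative quantities."""

    std_molecules_added: float
    relative_quantity_spiked: float
    relative_quantity_unspiked: float
    cells_per_reaction: float

    def __post_init__(self) -> None:
        if self.std_molecules_added < 0:
            raise ValidationError("std_molecules_added must be >= 0")
        if self.relative_quantity_spiked <= 0 or self.relative_quantity_unspiked <= 0:
            raise ValidationError("relative quantities must be > 0")
        if self.cells_per_reaction <= 0:
            raise ValidationError("cells_per_reaction must be > 0")


@dataclass(frozen=True)
class EfficiencyFit:
    """Amplification efficiency from a dilution series."""

    efficiency: float
    slope: float
    r_squared: float
    n_points: int


@dataclass
class TitrationFit:
    """Through-origin (or unconstrained) fit of spike ratio on standard added."""

    slope_per_molecule: float
    intercept: float
    r_squared: float
    endogenous_per_reaction: float
    endogenous_per_cell: float
    n_points: int
    negative_ratio_points: int = 0
    warnings: list[str] = field(default_factory=list)


def primer_efficiency(dilution_series: list[tuple[float, float]]) -> EfficiencyFit:
    """Amplification efficiency from a (log10 dilution, mean Cq) series.

    Fits Cq on log10(dilution) by least squares; E = 10^(-1/slope).
    A perfect doubling per cycle gives a slope of -3.3219 and E = 2.
    """
    if len(dilution_series) < 3:
        raise EstimationError("need >= 3 dilution points to estimate efficiency")
    x = np.asarray([p[0] for p in dilution_series], dtype=float)
    y = np.asarray([p[1] for p in dilution_series], dtype=float)
    if x.max() - x.min() < 2.0:
        raise EstimationError("dilution series must span >= 2 log10 units")
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise EstimationError(
            f"dilution slope must be negative (Cq rises as template falls), got {slope:.3g}"
        )
    resid = y - (slope * x + intercept)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    eff = 10.0 ** (-1.0 / slope)
    if not (1.0 < eff <= 2.2):
        raise EstimationError(f"efficiency {eff:.3f} outside the plausible (1, 2.2]")
    return EfficiencyFit(efficiency=eff, slope=float(slope), r_squared=r2, n_points=len(x))


def relative_quantity(
    cq_target: float,
    cq_reference: float,
    eff_target: float = 2.0,
    eff_reference: float = 2.0,
) -> float:
    """Efficiency-corrected reference-normalized quantity.

    Returns ``E_t^(-Cq_t) / E_r^(-Cq_r)`` — defined up to an arbitrary common
    scale, so only ratios between samples sharing target and reference are
    meaningful.
    """
    for eff in (eff_target, eff_reference):
        if not (1.0 < eff <= 2.2):
            raise ValidationError(f"efficiency must be in (1, 2.2], got {eff}")
    return eff_target ** (-cq_target) / eff_reference ** (-cq_reference)


def spike_ratio(point: TitrationPoint) -> float:
    """Calculated standard:endogenous ratio for one titration point.

    ``spiked/unspiked - 1``; exactly 1 when the spike doubles the measured
    quantity (the dashed-line condition where standard equals endogenous).
    Under noise the value may be <= 0; callers keep such points (truncation
    would bias the fit upward) but flag them.
    """
    if point.relative_quantity_unspiked <= 0:
        raise ValidationError("unspiked relative quantity must be > 0")
    return point.relative_quantity_spiked / point.relative_quantity_unspiked - 1.0


def fit_titration(
    points: list[TitrationPoint],
    weighting: str = "none",
    through_origin: bool = True,
) -> TitrationFit:
    """Fit the spike-in standard curve and invert it to copies per cell.

    Parameters
    ----------
    points
        Titration points; >= 3 with distinct standard amounts required.
    weighting
        ``"none"`` (default) or ``"inverse_s"`` (weights 1/S_i, emphasizing
        the low-spike points nearest the R = 1 crossing; S_i = 0 points get
        the largest finite weight present).
    through_origin
        Fit R = m*S (default; R = 0 at S = 0 by construction). When False an
        intercept is estimated and the endogenous amount is read where the
        fitted line crosses R = 1.
    """
    if len(points) < 3:
        raise EstimationError("need >= 3 titration points")
    s = np.asarray([p.std_molecules_added for p in points], dtype=float)
    if len(np.unique(s)) < 3:
        raise EstimationError("need >= 3 distinct standard amounts")
    if np.all(s == 0):
        raise EstimationError("all standard amounts are zero")
    r = np.asarray([spike_ratio(p) for p in points], dtype=float)
    cells = np.asarray([p.cells_per_reaction for p in points], dtype=float)
    warnings: list[str] = []
    if not np.allclose(cells, cells[0]):
        warnings.append("cells_per_reaction varies across points; using the mean")
    cells_per_reaction = float(cells.mean())

    if weighting == "none":
        w = np.ones_like(s)
    elif weighting == "inverse_s":
        pos = s[s > 0]
        w = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), 1.0 / pos.min())
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")

    n_neg = int(np.sum(r <= 0))
    if n_neg:
        warnings.append(f"{n_neg} titration point(s) with ratio <= 0 retained in fit")

    if through_origin:
        denom = float(np.sum(w * s * s))
        if denom == 0:
            raise EstimationError("degenerate design: no information in standard amounts")
        m = float(np.sum(w * s * r)) / denom
        intercept = 0.0
        fitted = m * s
        # uncentered R^2 (the natural choice for a no-intercept fit)
        tss = float(np.sum(w * r * r))
        r2 = 1.0 - float(np.sum(w * (r - fitted) ** 2)) / tss if tss > 0 else 1.0
    else:
        sw = np.sqrt(w)
        design = np.column_stack([np.ones_like(s), s])
        coef, *_ = np.linalg.lstsq(design * sw[:, None], r * sw, rcond=None)
        intercept, m = float(coef[0]), float(coef[1])
        fitted = intercept + m * s
        tss = float(np.sum(w * (r - np.average(r, weights=w)) ** 2))
        r2 = 1.0 - float(np.sum(w * (r - fitted) ** 2)) / tss if tss > 0 else 1.0

    if m <= 0:
        raise EstimationError(f"non-positive titration slope ({m:.3g}); cannot invert")
    endo_per_rxn = (1.0 - intercept) / m
    if endo_per_rxn <= 0:
        raise EstimationError("fitted line never reaches ratio 1 at positive spike")
    if not (r.min() < 1.0 < r.max()):
        warnings.append("titration does not bracket the ratio-1 crossing; extrapolating")

    return TitrationFit(
        slope_per_molecule=m,
        intercept=intercept,
        r_squared=max(min(r2, 1.0), 0.0) if math.isfinite(r2) else float("nan"),
        endogenous_per_reaction=endo_per_rxn,
        endogenous_per_cell=endo_per_rxn / cells_per_reaction,
        n_points=len(points),
        negative_ratio_points=n_neg,
        warnings=warnings,
    )


def aggregate_primer_pairs(estimates: list[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1) across per-primer-pair copy estimates.

    With a single estimate the SD is returned as NaN (undefined).
    """
    if len(estimates) == 0:
        raise ValidationError("no estimates to aggregate")
    arr = np.asarray(estimates, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    return mean, sd


def summarize_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Collapse Cq replicates to per-(sample, target) means with a QC flag.

    Expects columns ``sample_id, target, cq, replicate``. Groups whose Cq
    range exceeds 0.5 cycles are flagged, not dropped.
    """
    required = {"sample_id", "target", "cq"}
    missing = required - set(wells.columns)
    if missing:
        raise ValidationError(f"wells table missing columns: {sorted(missing)}")
    grouped = wells.groupby(["sample_id", "target"])["cq"].agg(["mean", "min", "max", "count"])
    grouped["range_flag"] = (grouped["max"] - grouped["min"]) > CQ_REPLICATE_RANGE_FLAG
    return grouped.reset_index().rename(columns={"mean": "cq_mean", "count": "n_replicates"})


def estimate_copies_from_tables(
    wells: pd.DataFrame,
    design: pd.DataFrame,
    target: str,
    reference: str,
    eff_target: float = 2.0,
    eff_reference: float = 2.0,
    weighting: str = "none",
    through_origin: bool = True,
) -> TitrationFit:
    """End-to-end estimate from the raw-well and titration-design tables.

    ``wells``: one row per well (``sample_id, target, cq, replicate``).
    ``design``: one row per sample (``sample_id, std_molecules_added,
    cells_per_reaction, spiked, paired_unspiked_id``).
    """
    cq = summarize_wells(wells).set_index(["sample_id", "target"])["cq_mean"]

    def rq(sample_id: str) -> float:
        try:
            cq_t = cq.loc[(sample_id, target)]
            cq_r = cq.loc[(sample_id, reference)]
        except KeyError as exc:
            raise ValidationError(f"missing wells for sample {sample_id!r}: {exc}") from exc
        return relative_quantity(cq_t, cq_r, eff_target, eff_reference)

    points = []
    for _, row in design[design["spiked"].astype(int) == 1].iterrows():
        points.append(
            TitrationPoint(
                std_molecules_added=float(row["std_molecules_added"]),
                relative_quantity_spiked=rq(str(row["sample_id"])),
                relative_quantity_unspiked=rq(str(row["paired_unspiked_id"])),
                cells_per_reaction=float(row["cells_per_reaction"]),
            )
        )
    return fit_titration(points, weighting=weighting, through_origin=through_origin)
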