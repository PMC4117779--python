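"""³⁵S-labeled protein standard: from translation-reaction recipe to molecules.

A protein standard for quantitative westerns is produced by in-vitro
translation in rabbit reticulocyte lysate (RRL) in the presence of
³⁵S-methionine. The number of standard molecules follows from mass balance
on the methionine pool:

1. The pool's specific radioactivity (dpm per pmol Met) is total label
   activity divided by total methionine — supplemented hot plus supplemented
   cold; endogenous RRL methionine is negligible next to the supplement and
   is off by default (an optional additive term is exposed).
2. Scintillation counts of (a fraction of) the labeled material, corrected
   for the fraction of radioactivity actually in the protein band
   (``band_purity``), divided by the pool SA gives pmol methionine in
   protein; dividing by methionines per protein molecule gives pmol protein,
   hence molecules.

The resulting standard calibrates western blots via the shared
densitometry machinery in :mod:`telquant.blot`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from . import blot
from .exceptions import ValidationError
from .units import AVOGADRO, activity_to_moles, cpm_to_dpm, uci_to_dpm


@dataclass(frozen=True)
class TranslationReaction:
    """Composition of an RRL translation reaction (volumes in μl).

    Defaults mirror a typical 500-μl preparative reaction supplemented with
    10 μl of 1.0 mM cold Met and 10 μl of a ³⁵S-Met stock supplied as
    1 mCi in 98 μl at 1175 Ci/mmol.
    """

    hot_met_volume_ul: float = 10.0
    hot_met_stock_activity_mci: float = 1.0
    hot_met_stock_volume_ul: float = 98.0
    hot_met_specific_activity_ci_per_mmol: float = 1175.0
    cold_met_volume_ul: float = 10.0
    cold_met_conc_mm: float = 1.0
    total_volume_ul: float = 500.0

    def __post_init__(self) -> None:
        for name in (
            "hot_met_volume_ul",
            "hot_met_stock_activity_mci",
            "hot_met_stock_volume_ul",
            "hot_met_specific_activity_ci_per_mmol",
            "total_volume_ul",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.cold_met_volume_ul < 0 or self.cold_met_conc_mm < 0:
            raise ValidationError("cold Met volume/concentration must be >= 0")

    @property
    def hot_met_activity_uci(self) -> float:
        """Activity of the hot-Met aliquot added to the reaction, in μCi."""
        return (
            self.hot_met_volume_ul
            * self.hot_met_stock_activity_mci
            * 1000.0
            / self.hot_met_stock_volume_ul
        )


@dataclass(frozen=True)
class ScintillationMeasurement:
    """A scintillation-counter reading of part of a labeled preparation."""

    sample_id: str
    cpm: float
    fraction_of_reaction: float = 1.0
    counting_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.cpm < 0:
            raise ValidationError("cpm must be >= 0")
        if not (0 < self.fraction_of_reaction <= 1):
            raise ValidationError("fraction_of_reaction must be in (0, 1]")
        if not (0 < self.counting_efficiency <= 1):
            raise ValidationError("counting_efficiency must be in (0, 1]")


@dataclass(frozen=True)
class MetPool:
    """The methionine pool of a translation reaction."""

    hot_pmol: float
    cold_pmol: float
    endogenous_pmol: float
    total_dpm: float

    @property
    def total_pmol(self) -> float:
        return self.hot_pmol + self.cold_pmol + self.endogenous_pmol

    @property
    def sa_dpm_per_pmol(self) -> float:
        return self.total_dpm / self.total_pmol


@dataclass(frozen=True)
class ProteinStandard:
    """A quantified protein standard preparation."""

    molecules: float
    met_per_protein: int
    band_purity_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.molecules < 0:
            raise ValidationError("molecules must be >= 0")
        if self.met_per_protein < 1:
            raise ValidationError("met_per_protein must be >= 1")
        if not (0 < self.band_purity_fraction <= 1):
            raise ValidationError("band_purity_fraction must be in (0, 1]")


def met_pool_specific_activity(
    rxn: TranslationReaction, endogenous_met_pmol: float = 0.0
) -> MetPool:
    """Specific radioactivity of the reaction's methionine pool.

    Hot Met pmol comes from the aliquot activity and the stock's Ci/mmol;
    cold Met pmol from volume x concentration (μl x mM = nmol -> pmol).
    ``endogenous_met_pmol`` adds lysate methionine for sensitivity analysis;
    the default 0 reflects its validated negligibility relative to the
    supplement.
    """
    if endogenous_met_pmol < 0:
        raise ValidationError("endogenous_met_pmol must be >= 0")
    hot_uci = rxn.hot_met_activity_uci
    hot_pmol = activity_to_moles(hot_uci, rxn.hot_met_specific_activity_ci_per_mmol)
    cold_pmol = rxn.cold_met_volume_ul * rxn.cold_met_conc_mm * 1000.0
    pool = MetPool(
        hot_pmol=hot_pmol,
        cold_pmol=cold_pmol,
        endogenous_pmol=endogenous_met_pmol,
        total_dpm=uci_to_dpm(hot_uci),
    )
    if pool.total_pmol <= 0:
        raise ValidationError("methionine pool is empty")
    return pool


def molecules_from_cpm(
    meas: ScintillationMeasurement,
    sa_met_dpm_per_pmol: float,
    met_per_protein: int,
    band_purity: float = 0.9,
) -> float:
    """Protein molecules in the whole preparation from one scintillation count.

    dpm in protein = cpm/efficiency x band_purity; pmol Met = dpm / pool SA;
    pmol protein = pmol Met / Met residues per molecule; scaled up by
    1/fraction_of_reaction to whole-prep terms and converted to molecules.
    """
    if sa_met_dpm_per_pmol <= 0:
        raise ValidationError("sa_met_dpm_per_pmol must be > 0")
    if met_per_protein < 1:
        raise ValidationError("met_per_protein must be >= 1")
    if not (0 < band_purity <= 1):
        raise ValidationError("band_purity must be in (0, 1]")
    dpm = cpm_to_dpm(meas.cpm, meas.counting_efficiency) * band_purity
    pmol_protein = dpm / sa_met_dpm_per_pmol / met_per_protein
    pmol_whole_prep = pmol_protein / meas.fraction_of_reaction
    return pmol_whole_prep * 1e-12 * AVOGADRO


def count_methionines(fasta: str | Path) -> int:
    """Number of Met residues in the first record of a protein FASTA.

    Accepts a path or raw FASTA text. The initiator Met is included — it is
    labeled like any other residue.
    """
    is_path = isinstance(fasta, Path) or (
        isinstance(fasta, str) and fasta and "\n" not in fasta and Path(fasta).is_file()
    )
    if is_path:
        records = list(SeqIO.parse(str(fasta), "fasta"))
    else:
        records = list(SeqIO.parse(io.StringIO(str(fasta)), "fasta"))
    if not records:
        raise ValidationError("no FASTA records found")
    return str(records[0].seq).upper().count("M")


def western_calibration(
    standard_lanes: list[blot.LaneMeasurement],
    sample_lanes: list[blot.LaneMeasurement],
    force_origin: bool = True,
) -> dict[str, dict]:
    """Quantify elution lanes against the protein-standard titration.

    Returns per-lane molecules and molecules/μl elution, with extrapolation
    flags inherited from the blot standard curve.
    """
    curve = blot.fit_standard_curve(standard_lanes, force_origin=force_origin)
    out: dict[str, dict] = {}
    for lane in sample_lanes:
        est = blot.quantify_band(lane.signal, curve)
        entry = {
            "molecules": est.molecules,
            "extrapolated": est.extrapolated,
            "flags": list(est.flags),
        }
        if lane.signal == 0:
            entry["flags"].append("zero signal lane")
        if lane.elution_volume_ul:
            entry["molecules_per_ul"] = blot.molecules_per_ul(
                est.molecules, lane.elution_volume_ul
            )
        out[lane.lane_id] = entry
    return out
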