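"""Unit-safe conversions between mass, moles, molecules and radioactivity.

Every downstream stage (spike-in qPCR, blot calibration, ³⁵S protein
standards, the direct extension assay) reduces to bookkeeping between
picograms, picomoles, molecule counts and scintillation counts. The
conversions here are deliberately narrow: a closed unit vocabulary, strict
argument validation, and exact round-trips, rather than a general unit
system.

Conventions
-----------
* 1 Ci = 2.22e12 dpm, hence 1 μCi = 2.22e6 dpm (exact, by definition of
  the curie at 3.7e10 Bq).
* RNA molar mass is modelled as ``length_nt * mean_residue_mass + end
  correction``; the defaults (320.5 Da per residue, +159 Da for a
  5'-triphosphate/3'-OH transcript) reproduce standard in-vitro-transcript
  calculators.
* Scintillation counts: dpm = cpm / counting_efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError

AVOGADRO = 6.02214076e23
"""Molecules per mole (CODATA 2018 exact value)."""

DPM_PER_UCI = 2.22e6
"""Disintegrations per minute per microcurie (exact)."""

MEAN_RNA_RESIDUE_MASS_DA = 320.5
RNA_END_CORRECTION_DA = 159.0

#: Closed vocabulary of units handled by :class:`Amount`.
UNIT_VOCABULARY = frozenset(
    {
        "molecules",
        "pmol",
        "nmol",
        "pg",
        "ng",
        "uCi",
        "dpm",
        "cpm",
        "molecules_per_cell",
        "molecules_per_ul",
        "uM",
    }
)


@dataclass(frozen=True)
class Amount:
    """A non-negative physical quantity tagged with one of the known units."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNIT_VOCABULARY:
            raise ValidationError(
                f"unknown unit {self.unit!r}; allowed: {sorted(UNIT_VOCABULARY)}"
            )
        if not (self.value >= 0):
            raise ValidationError(f"amount must be >= 0, got {self.value}")


@dataclass(frozen=True)
class RnaSpecies:
    """An RNA species for mass <-> molecule conversions.

    Parameters
    ----------
    name
        Display label (e.g. ``"hTR"``).
    length_nt
        Transcript length in nucleotides.
    mean_residue_mass_da
        Average mass per incorporated nucleotide residue.
    end_correction_da
        Additive end-group correction for a 5'-triphosphate/3'-OH
        in-vitro transcript.
    """

    name: str
    length_nt: int
    mean_residue_mass_da: float = MEAN_RNA_RESIDUE_MASS_DA
    end_correction_da: float = RNA_END_CORRECTION_DA

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValidationError(f"length_nt must be positive, got {self.length_nt}")
        if self.molar_mass_da <= 0:
            raise ValidationError("RNA molar mass must be positive")

    @property
    def molar_mass_da(self) -> float:
        """Molar mass in g/mol (Da)."""
        return self.length_nt * self.mean_residue_mass_da + self.end_correction_da


#: Human telomerase RNA; the canonical 451-nt mature transcript.
HTR = RnaSpecies("hTR", length_nt=451)


def rna_mass_to_molecules(mass_pg: float, species: RnaSpecies) -> float:
    """Convert picograms of an RNA species to a molecule count.

    Example: 2 pg of the 451-nt hTR transcript is ~8.3e6 molecules, the
    northern-blot detection limit used to bound hTR in telomerase-negative
    cells.
    """
    if mass_pg < 0:
        raise ValidationError(f"mass_pg must be >= 0, got {mass_pg}")
    return mass_pg * 1e-12 / species.molar_mass_da * AVOGADRO


def rna_molecules_to_mass(molecules: float, species: RnaSpecies) -> float:
    """Inverse of :func:`rna_mass_to_molecules`; returns picograms."""
    if molecules < 0:
        raise ValidationError(f"molecules must be >= 0, got {molecules}")
    return molecules / AVOGADRO * species.molar_mass_da * 1e12


def activity_to_moles(activity_uci: float, specific_activity_ci_per_mmol: float) -> float:
    """Moles (pmol) of a radiolabeled compound from its activity.

    Parameters
    ----------
    activity_uci
        Total activity of the aliquot in μCi.
    specific_activity_ci_per_mmol
        Specific radioactivity of the labeled stock in Ci/mmol
        (e.g. 3000 Ci/mmol for [α-³²P]-dGTP, 1175 Ci/mmol for ³⁵S-Met).

    Returns
    -------
    float
        Amount in pmol. 30 μCi at 3000 Ci/mmol -> 10 pmol.
    """
    if specific_activity_ci_per_mmol <= 0:
        raise ValidationError(
            f"specific activity must be > 0, got {specific_activity_ci_per_mmol}"
        )
    if activity_uci < 0:
        raise ValidationError(f"activity must be >= 0, got {activity_uci}")
    # μCi -> Ci -> mmol -> pmol
    return activity_uci * 1e-6 / specific_activity_ci_per_mmol * 1e9


def uci_to_dpm(activity_uci: float) -> float:
    """μCi -> disintegrations per minute (1 μCi = 2.22e6 dpm exactly)."""
    if activity_uci < 0:
        raise ValidationError(f"activity must be >= 0, got {activity_uci}")
    return activity_uci * DPM_PER_UCI


def cpm_to_dpm(cpm: float, counting_efficiency: float = 1.0) -> float:
    """Counts per minute -> disintegrations per minute.

    ``counting_efficiency`` is the scintillation counter's detection
    probability per disintegration; with the default 1.0 this is the
    identity.
    """
    if not (0 < counting_efficiency <= 1):
        raise ValidationError(
            f"counting efficiency must be in (0, 1], got {counting_efficiency}"
        )
    if cpm < 0:
        raise ValidationError(f"cpm must be >= 0, got {cpm}")
    return cpm / counting_efficiency


def dpm_to_cpm(dpm: float, counting_efficiency: float = 1.0) -> float:
    """Inverse of :func:`cpm_to_dpm`."""
    if not (0 < counting_efficiency <= 1):
        raise ValidationError(
            f"counting efficiency must be in (0, 1], got {counting_efficiency}"
        )
    if dpm < 0:
        raise ValidationError(f"dpm must be >= 0, got {dpm}")
    return dpm * counting_efficiency


def decay_fraction_remaining(elapsed_days: float, half_life_days: float) -> float:
    """Fraction of a radioisotope remaining after ``elapsed_days``."""
    if half_life_days <= 0:
        raise ValidationError("half-life must be positive")
    return 2.0 ** (-elapsed_days / half_life_days)


S35_HALF_LIFE_DAYS = 87.4
P32_HALF_LIFE_DAYS = 14.26
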