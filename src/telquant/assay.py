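"""Absolute telomerase activity from the direct primer-extension assay.

A telomeric DNA primer is extended by telomerase in the presence of
[α-³²P]-dGTP; products are resolved on a denaturing gel next to a 5'-labeled
18-mer loading control (LC) whose absolute radioactivity was measured by
scintillation counting. The chain to a specific activity is:

1. **dGTP pool** — cold dGTP from the assay buffer plus hot dGTP from the
   labeled stock give the pool concentration and its specific radioactivity
   (dpm per pmol dGTP).
2. **Product radioactivity** — gel signal of the product ladder relative to
   the LC band, times the LC's known cpm (corrected for the ~90% of LC
   radioactivity actually in the 18-mer band), gives product cpm; the gel's
   arbitrary signal scale cancels.
3. **Nucleotides incorporated** — product dpm over pool SA gives pmol dGMP;
   dividing by the G fraction of the telomeric repeat (0.5 for TTAGGG)
   gives total nucleotides.
4. **Specific activity** — total nucleotides per enzyme in the reaction per
   minute. The enzyme count comes from the elution hTR measurement (hTR in
   the IP elution counts telomerase monomers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EstimationError, ValidationError
from .units import AVOGADRO, activity_to_moles, cpm_to_dpm, uci_to_dpm


@dataclass(frozen=True)
class AssayRecipe:
    """Direct-assay reaction composition (defaults: the standard recipe).

    30 μl enzyme sample plus 20 μl assay buffer (25 μM cold dGTP) plus 3 μl
    hot dGTP at 10 μCi/μl, 3000 Ci/mmol, for ~10 μM total dGTP in 50 μl.
    """

    reaction_volume_ul: float = 50.0
    buffer_volume_ul: float = 20.0
    buffer_cold_dgtp_um: float = 25.0
    hot_dgtp_volume_ul: float = 3.0
    hot_dgtp_uci_per_ul: float = 10.0
    hot_dgtp_ci_per_mmol: float = 3000.0
    duration_min: float = 120.0
    temperature_c: float = 37.0
    repeat_unit: str = "TTAGGG"

    def __post_init__(self) -> None:
        if self.reaction_volume_ul <= 0 or self.buffer_volume_ul <= 0:
            raise ValidationError("volumes must be > 0")
        if self.buffer_volume_ul + self.hot_dgtp_volume_ul > self.reaction_volume_ul:
            raise ValidationError("component volumes exceed reaction volume")
        if self.duration_min <= 0:
            raise ValidationError("duration must be > 0")
        if not self.repeat_unit:
            raise ValidationError("repeat_unit must be non-empty")


@dataclass(frozen=True)
class DgtpPool:
    """The assay's dGTP pool: concentration and specific radioactivity."""

    total_conc_um: float
    hot_fraction: float
    specific_activity_dpm_per_pmol: float
    total_pmol: float


@dataclass(frozen=True)
class GelQuantification:
    """Densitometry and bookkeeping for one direct-assay gel lane."""

    products_signal_au: float
    lc_signal_au: float
    lc_cpm: float
    lc_band_fraction: float = 0.9
    n_telomerase_molecules: float = 0.0
    fraction_of_elution_assayed: float = 1.0
    counting_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.products_signal_au < 0 or self.lc_signal_au < 0:
            raise ValidationError("gel signals must be >= 0")
        if self.lc_cpm <= 0:
            raise ValidationError("lc_cpm must be > 0")
        if not (0 < self.lc_band_fraction <= 1):
            raise ValidationError("lc_band_fraction must be in (0, 1]")
        if not (0 < self.fraction_of_elution_assayed <= 1):
            raise ValidationError("fraction_of_elution_assayed must be in (0, 1]")


@dataclass
class LinearityResult:
    """Origin-forced linear fit of a validation series with deviation flags."""

    slope: float
    max_relative_deviation: float
    passed: bool
    flagged_indices: list[int] = field(default_factory=list)


def g_fraction(repeat_unit: str) -> float:
    """Fraction of G residues in the telomeric repeat (0.5 for TTAGGG)."""
    if not repeat_unit:
        raise ValidationError("repeat_unit must be non-empty")
    f = repeat_unit.upper().count("G") / len(repeat_unit)
    if f == 0:
        raise ValidationError("repeat unit contains no G; dGMP labeling impossible")
    return f


def dgtp_pool(recipe: AssayRecipe) -> DgtpPool:
    """Compute the dGTP pool from the assay recipe.

    With the default recipe: 500 pmol cold + 10 pmol hot in 50 μl, i.e.
    ~10 μM total dGTP, with a pool SA of ~1.3e5 dpm/pmol.
    """
    cold_pmol = recipe.buffer_volume_ul * recipe.buffer_cold_dgtp_um  # μl x μM = pmol
    hot_uci = recipe.hot_dgtp_volume_ul * recipe.hot_dgtp_uci_per_ul
    hot_pmol = (
        activity_to_moles(hot_uci, recipe.hot_dgtp_ci_per_mmol) if hot_uci > 0 else 0.0
    )
    total_pmol = cold_pmol + hot_pmol
    if total_pmol <= 0:
        raise ValidationError("recipe contains no dGTP")
    return DgtpPool(
        total_conc_um=total_pmol / recipe.reaction_volume_ul,
        hot_fraction=hot_pmol / total_pmol,
        specific_activity_dpm_per_pmol=uci_to_dpm(hot_uci) / total_pmol,
        total_pmol=total_pmol,
    )


def product_cpm(gel: GelQuantification) -> float:
    """Absolute cpm in the extension-product ladder, via the LC calibration.

    ``products_signal/lc_signal x lc_cpm x lc_band_fraction`` — the gel's
    arbitrary densitometry scale cancels in the signal ratio.
    """
    if gel.lc_signal_au <= 0:
        raise ValidationError("lc_signal must be > 0")
    return gel.products_signal_au / gel.lc_signal_au * gel.lc_cpm * gel.lc_band_fraction


def nucleotides_incorporated(
    prod_cpm: float,
    pool: DgtpPool,
    repeat_unit: str = "TTAGGG",
    counting_efficiency: float = 1.0,
) -> float:
    """Total nucleotides (pmol) incorporated, from product radioactivity.

    dGMP pmol = product dpm / pool SA; total nt = dGMP / f_G where f_G is
    the G content of the repeat. Uses the asymptotic repeat composition; the
    error from the first (permuted) repeat on the primer is small for
    products of two or more repeats.
    """
    if pool.specific_activity_dpm_per_pmol <= 0:
        raise ValidationError("pool specific activity must be > 0")
    if prod_cpm < 0:
        raise ValidationError("product cpm must be >= 0")
    dpm = cpm_to_dpm(prod_cpm, counting_efficiency)
    dgmp_pmol = dpm / pool.specific_activity_dpm_per_pmol
    return dgmp_pmol / g_fraction(repeat_unit)


def specific_activity(
    total_nt_pmol: float, n_telomerase: float, duration_min: float
) -> float:
    """Nucleotides incorporated per telomerase monomer per minute.

    ``n_telomerase`` is the number of enzyme molecules present in the
    reaction that produced ``total_nt_pmol``.
    """
    if n_telomerase <= 0:
        raise ValidationError("n_telomerase must be > 0")
    if duration_min <= 0:
        raise ValidationError("duration must be > 0")
    if total_nt_pmol < 0:
        raise ValidationError("total_nt_pmol must be >= 0")
    nt_molecules = total_nt_pmol * 1e-12 * AVOGADRO
    return nt_molecules / n_telomerase / duration_min


def assay_specific_activity(
    gel: GelQuantification, pool: DgtpPool, duration_min: float, repeat_unit: str = "TTAGGG"
) -> float:
    """End-to-end specific activity for one assay lane.

    The enzyme count in the reaction is ``n_telomerase_molecules x
    fraction_of_elution_assayed``; because the measured products come from
    that same fraction, the result is invariant to the fraction assayed only
    when ``n_telomerase_molecules`` is the whole-elution count — which is the
    convention here.
    """
    if gel.n_telomerase_molecules <= 0:
        raise ValidationError("n_telomerase_molecules must be > 0")
    nt = nucleotides_incorporated(
        product_cpm(gel), pool, repeat_unit, gel.counting_efficiency
    )
    n_in_reaction = gel.n_telomerase_molecules * gel.fraction_of_elution_assayed
    return specific_activity(nt, n_in_reaction, duration_min)


def linearity_check(
    series: list[tuple[float, float]],
    kind: str = "time_course",
    threshold: float = 0.15,
) -> LinearityResult:
    """Check a validation series (time course or enzyme titration) for linearity.

    Fits an origin-forced line and flags points whose relative deviation from
    it exceeds ``threshold``. Saturating (Michaelis-shaped) enzyme titrations
    and single outliers both trip the flag.
    """
    if kind not in ("time_course", "enzyme_titration"):
        raise ValidationError(f"unknown series kind {kind!r}")
    if len(series) < 3:
        raise EstimationError("need >= 3 points for a linearity check")
    x = np.asarray([p[0] for p in series], dtype=float)
    y = np.asarray([p[1] for p in series], dtype=float)
    denom = float(np.sum(x * x))
    if denom == 0:
        raise EstimationError("all x values are zero")
    slope = float(np.sum(x * y)) / denom
    if slope <= 0:
        raise EstimationError("non-positive slope in linearity series")
    rel = np.zeros_like(y)
    nonzero = x != 0
    rel[nonzero] = np.abs(y[nonzero] - slope * x[nonzero]) / (slope * x[nonzero])
    flagged = [int(i) for i in np.nonzero(rel > threshold)[0]]
    return LinearityResult(
        slope=slope,
        max_relative_deviation=float(rel.max()),
        passed=not flagged,
        flagged_indices=flagged,
    )


def fold_change_activity(
    condition_a: float,
    condition_b: float,
    sd_a: float | None = None,
    sd_b: float | None = None,
) -> tuple[float, float]:
    """Activity fold change b/a with first-order (delta-method) SD.

    Returns ``(fold, sd)``; sd is NaN when either input SD is missing.
    """
    if condition_a <= 0:
        raise ValidationError("condition_a must be > 0")
    if condition_b < 0:
        raise ValidationError("condition_b must be >= 0")
    fold = condition_b / condition_a
    if sd_a is None or sd_b is None:
        return fold, float("nan")
    sd = fold * np.sqrt((sd_a / condition_a) ** 2 + (sd_b / condition_b) ** 2)
    return fold, float(sd)
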