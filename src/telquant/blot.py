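"""Quantitative northern/western blot densitometry.

Band signals are calibrated against a titration of standard molecules run
on the same gel: a least-squares standard curve (origin-forced by default,
since zero molecules gives zero background-subtracted signal) converts
sample-band signal to molecules, and dividing by the number of cells loaded
gives molecules per cell. Signals outside the standards' range are flagged
as extrapolated rather than suppressed. A detection-limit helper turns the
faintest detectable standard into an upper bound for blank samples.

Inputs are net (background-subtracted) signals from densitometry software;
image analysis is upstream of this module. For targets running as a doublet
(as hTR does under incomplete denaturation), sum the two band signals into
one lane measurement before calling in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EstimationError, ValidationError

ROLES = ("standard", "sample", "internal_control")


@dataclass(frozen=True)
class LaneMeasurement:
    """One background-subtracted band signal with its lane metadata."""

    lane_id: str
    target: str
    signal: float
    role: str
    std_molecules: float | None = None
    cells_loaded: float | None = None
    elution_volume_ul: float | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValidationError(f"signal must be >= 0, got {self.signal}")
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role == "standard" and not (self.std_molecules and self.std_molecules > 0):
            raise ValidationError("standard lanes require std_molecules > 0")
        if self.role == "sample":
            has_cells = self.cells_loaded is not None and self.cells_loaded > 0
            has_volume = self.elution_volume_ul is not None and self.elution_volume_ul > 0
            if not (has_cells or has_volume):
                raise ValidationError(
                    "sample lanes require cells_loaded > 0 or elution_volume_ul > 0"
                )


@dataclass(frozen=True)
class StandardCurve:
    """Signal-vs-molecules calibration line from standard lanes."""

    slope_signal_per_molecule: float
    intercept: float
    r_squared: float
    linear_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope_signal_per_molecule <= 0:
            raise ValidationError("standard-curve slope must be > 0")
        if not self.linear_range[0] < self.linear_range[1]:
            raise ValidationError("linear_range must satisfy min < max")


@dataclass
class BandEstimate:
    """Molecules inferred for one band, with QC flags."""

    molecules: float
    extrapolated: bool = False
    clamped: bool = False
    flags: list[str] = field(default_factory=list)


def fit_standard_curve(
    standards: list[LaneMeasurement], force_origin: bool = True
) -> StandardCurve:
    """Least-squares line of signal on molecules over the standard lanes."""
    stds = [l for l in standards if l.role == "standard"]
    molecules = np.asarray([l.std_molecules for l in stds], dtype=float)
    if len(np.unique(molecules)) < 2:
        raise EstimationError("need >= 2 standard lanes with distinct molecule amounts")
    signal = np.asarray([l.signal for l in stds], dtype=float)

    if force_origin:
        slope = float(np.sum(molecules * signal) / np.sum(molecules**2))
        intercept = 0.0
        fitted = slope * molecules
        tss = float(np.sum(signal**2))
    else:
        intercept, slope = (
            float(c) for c in np.linalg.lstsq(
                np.column_stack([np.ones_like(molecules), molecules]), signal, rcond=None
            )[0]
        )
        fitted = intercept + slope * molecules
        tss = float(np.sum((signal - signal.mean()) ** 2))
    if slope <= 0:
        raise EstimationError(f"non-positive standard-curve slope ({slope:.3g})")
    r2 = 1.0 - float(np.sum((signal - fitted) ** 2)) / tss if tss > 0 else 1.0
    return StandardCurve(
        slope_signal_per_molecule=slope,
        intercept=intercept,
        r_squared=max(0.0, min(1.0, r2)),
        linear_range=(float(signal.min()), float(signal.max())),
    )


def quantify_band(signal: float, curve: StandardCurve) -> BandEstimate:
    """Invert the standard curve for one band signal.

    Signals outside the standards' linear range are converted anyway but
    flagged ``extrapolated``; a negative inversion (possible with a free
    intercept) is clamped to zero with a flag.
    """
    if signal < 0:
        raise ValidationError(f"signal must be >= 0, got {signal}")
    est = BandEstimate(molecules=(signal - curve.intercept) / curve.slope_signal_per_molecule)
    lo, hi = curve.linear_range
    if not (lo <= signal <= hi):
        est.extrapolated = True
        est.flags.append(f"signal {signal:.3g} outside standards' linear range [{lo:.3g}, {hi:.3g}]")
    if est.molecules < 0:
        est.molecules = 0.0
        est.clamped = True
        est.flags.append("negative inversion clamped to 0")
    return est


def copies_per_cell(molecules: float, cells_loaded: float) -> float:
    """Molecules per cell from a lane loaded with a counted number of cells."""
    if cells_loaded <= 0:
        raise ValidationError(f"cells_loaded must be > 0, got {cells_loaded}")
    if molecules < 0:
        raise ValidationError(f"molecules must be >= 0, got {molecules}")
    return molecules / cells_loaded


def molecules_per_ul(molecules: float, elution_volume_ul: float) -> float:
    """Concentration of an elution lane in molecules per microliter."""
    if elution_volume_ul <= 0:
        raise ValidationError("elution_volume_ul must be > 0")
    return molecules / elution_volume_ul


def detection_limit_bound(limit_molecules: float, cells_loaded: float) -> float:
    """Upper-bound copies/cell for a sample with no detectable band.

    The faintest detectable standard (``limit_molecules``) divided by the
    number of cells loaded; e.g. an 8.3e6-molecule detection limit over 1e6
    cells bounds the target below ~8.3 copies per cell.
    """
    if limit_molecules < 0:
        raise ValidationError("limit_molecules must be >= 0")
    if cells_loaded <= 0:
        raise ValidationError("cells_loaded must be > 0")
    return limit_molecules / cells_loaded


def control_normalize(
    sample_signal: float, control_signal: float, reference_control_signal: float
) -> float:
    """Rescale a sample signal by its lane's internal-control recovery.

    Multiplies by ``reference_control / control``, the loading/transfer
    correction from an internal-control band (e.g. H1 RNA on northerns,
    β-actin on westerns). Identity when the controls are equal.
    """
    if control_signal <= 0 or reference_control_signal <= 0:
        raise ValidationError("control signals must be > 0")
    if sample_signal < 0:
        raise ValidationError("sample signal must be >= 0")
    return sample_signal * reference_control_signal / control_signal
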