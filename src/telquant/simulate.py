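"""Synthetic raw measurements for every stage of the pipeline.

Given a known per-cell ground truth, this module fabricates the raw tables
each analysis module consumes — qPCR wells, blot lanes, IP fraction
measurements, direct-assay gel quantifications and dGTP titrations — with a
configurable noise structure (additive Gaussian Cq noise, multiplicative
lognormal densitometry noise, Poisson scintillation counting). Every
estimator in the package has a noiseless scenario under which it is exact,
which is what makes parameter-recovery testing possible without any
laboratory data.

Assembly of the RNA and protein subunits into active enzyme is modelled as
a bimolecular equilibrium in an implicit fixed cell volume, so the
dissociation constant is expressed in molecules/cell and the assembled
count is the smaller root of the binding quadratic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import assay as assay_mod
from . import kinetics as kinetics_mod
from .blot import LaneMeasurement
from .exceptions import ValidationError
from .inventory import DepletionRatios, ElutionStoichiometry
from .units import AVOGADRO


@dataclass(frozen=True)
class GroundTruth:
    """True per-cell counts and enzyme parameters driving a simulation."""

    n_htr_per_cell: float
    n_htert_per_cell: float
    n_rnp_per_cell: float
    specific_activity_nt_min: float = 20.0
    km_um: float = 17.0
    vmax_nt_min: float = 59.0

    def __post_init__(self) -> None:
        for name in (
            "n_htr_per_cell",
            "n_htert_per_cell",
            "n_rnp_per_cell",
            "specific_activity_nt_min",
            "km_um",
            "vmax_nt_min",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_rnp_per_cell > min(self.n_htr_per_cell, self.n_htert_per_cell):
            raise ValidationError("n_rnp cannot exceed either subunit total")


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes for the raw-measurement generators.

    Defaults are conventional bench values: 0.15-cycle Cq scatter, 10%
    lognormal densitometry scatter, Poisson scintillation counting.
    """

    sigma_cq: float = 0.15
    blot_lognormal_sigma: float = 0.1
    poisson_counting: bool = True
    ip_efficiency: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_cq < 0 or self.blot_lognormal_sigma < 0:
            raise ValidationError("noise sigmas must be >= 0")
        if not (0 < self.ip_efficiency <= 1):
            raise ValidationError("ip_efficiency must be in (0, 1]")


NOISELESS = NoiseModel(sigma_cq=0.0, blot_lognormal_sigma=0.0, poisson_counting=False)

#: Implied equilibrium dissociation constant (molecules/cell) for the
#: baseline inventory 800 hTR / 280 hTERT / 240 RNP: Kd = (A-x)(B-x)/x.
_BASELINE_KD = (800.0 - 240.0) * (280.0 - 240.0) / 240.0


def preset(name: str) -> GroundTruth:
    """Named ground-truth scenarios.

    ``hek293t_like`` and ``hela_like`` use the measured per-cell inventories
    of those lines; ``va13_like`` is a telomerase-negative line (no hTR);
    ``super_telomerase`` overexpresses hTR 60x and hTERT 10x over the
    HEK-293T-like baseline and re-assembles via the equilibrium model.
    """
    if name == "hek293t_like":
        return GroundTruth(800.0, 280.0, 240.0)
    if name == "hela_like":
        return GroundTruth(1300.0, 500.0, 240.0)
    if name == "va13_like":
        return GroundTruth(0.0, 0.0, 0.0)
    if name == "super_telomerase":
        a, b = 800.0 * 60, 280.0 * 10
        x = equilibrium_assembly(a, b, _BASELINE_KD)
        return GroundTruth(a, b, x)
    raise ValidationError(f"unknown preset {name!r}")


def equilibrium_assembly(total_htr: float, total_htert: float, kd_molecules: float) -> float:
    """Assembled RNP at equilibrium for subunit totals A, B and Kd.

    The smaller root of x² - (A+B+Kd)x + AB = 0, computed in the
    numerically stable form 2AB / (s + sqrt(s² - 4AB)); satisfies
    0 <= x <= min(A, B), equals min(A, B) at Kd = 0, and is strictly
    increasing in either subunit total.
    """
    if total_htr < 0 or total_htert < 0 or kd_molecules < 0:
        raise ValidationError("subunit totals and Kd must be >= 0")
    ab = total_htr * total_htert
    if ab == 0:
        return 0.0
    s = total_htr + total_htert + kd_molecules
    disc = s * s - 4.0 * ab
    return 2.0 * ab / (s + math.sqrt(max(disc, 0.0)))


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_qpcr_titration(
    truth: GroundTruth,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator | None = 0,
    cells_per_reaction: float = 2000.0,
    spike_multiples: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    n_cq_replicates: int = 3,
    efficiency: float = 2.0,
    baseline_cq: float = 38.0,
    reference_cq: float = 18.0,
    target: str = "hTR_1",
    reference: str = "GAPDH",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spike-in titration experiment: (wells, design) tables.

    Standard amounts are ``spike_multiples`` times the true endogenous
    content per reaction; each spiked sample has a matched unspiked sample
    sharing cells and reference level. Cq = baseline - log_E(copies) + noise.
    """
    rng = _rng(seed)
    endo = truth.n_htr_per_cell * cells_per_reaction
    if endo <= 0:
        raise ValidationError("qPCR titration requires a positive endogenous count")
    wells, design = [], []
    log_e = math.log(efficiency)

    def add_wells(sample_id: str, copies: float) -> None:
        cq_true = baseline_cq - math.log(copies) / log_e
        for rep in range(1, n_cq_replicates + 1):
            wells.append(
                {
                    "sample_id": sample_id,
                    "target": target,
                    "cq": cq_true + rng.normal(0.0, noise.sigma_cq),
                    "replicate": rep,
                }
            )
            wells.append(
                {
                    "sample_id": sample_id,
                    "target": reference,
                    "cq": reference_cq + rng.normal(0.0, noise.sigma_cq),
                    "replicate": rep,
                }
            )

    for i, mult in enumerate(spike_multiples):
        std = mult * endo
        spiked_id, unspiked_id = f"spike_{i}", f"unspiked_{i}"
        add_wells(spiked_id, endo + std)
        add_wells(unspiked_id, endo)
        design.append(
            {
                "sample_id": spiked_id,
                "std_molecules_added": std,
                "cells_per_reaction": cells_per_reaction,
                "spiked": 1,
                "paired_unspiked_id": unspiked_id,
            }
        )
        design.append(
            {
                "sample_id": unspiked_id,
                "std_molecules_added": 0.0,
                "cells_per_reaction": cells_per_reaction,
                "spiked": 0,
                "paired_unspiked_id": "",
            }
        )
    return pd.DataFrame(wells), pd.DataFrame(design)


def simulate_ip(
    truth: GroundTruth,
    epsilon: float,
    noise: NoiseModel = NOISELESS,
    seed: int | np.random.Generator | None = 0,
    cells: float = 1e6,
    elution_volume_ul: float = 100.0,
    pull_free_tert: bool = False,
) -> dict:
    """One antibody pull-down experiment against the protein subunit.

    Bead-bound material is ``epsilon`` times the assembled pool (plus,
    optionally, epsilon times the free protein pool, modelling an antibody
    that captures free protein equally well); flow-through = input - bound
    exactly before measurement noise. Activity units are arbitrary
    (1 per assembled RNP). Returns the fraction table, the depletion
    ratios and the elution stoichiometry.
    """
    if not (0 < epsilon <= 1):
        raise ValidationError("epsilon must be in (0, 1]")
    rng = _rng(seed)
    n_rnp = truth.n_rnp_per_cell * cells
    n_htr = truth.n_htr_per_cell * cells
    n_htert = truth.n_htert_per_cell * cells
    free_tert = n_htert - n_rnp

    bound = {
        "activity": epsilon * n_rnp,
        "hTR": epsilon * n_rnp,  # free hTR carries no antibody epitope
        "hTERT": epsilon * (n_rnp + (free_tert if pull_free_tert else 0.0)),
    }
    inputs = {"activity": n_rnp, "hTR": n_htr, "hTERT": n_htert}
    rows = []
    for species in ("activity", "hTR", "hTERT"):
        ft = inputs[species] - bound[species]  # conservation, exact
        for fraction, expected in (
            ("input", inputs[species]),
            ("flow_through", ft),
            ("elution", bound[species]),
        ):
            measured = expected
            if noise.poisson_counting and expected > 0:
                measured = float(rng.poisson(expected))
            rows.append(
                {
                    "species": species,
                    "fraction": fraction,
                    "expected": expected,
                    "measured": measured,
                }
            )
    table = pd.DataFrame(rows)
    m = table.set_index(["species", "fraction"])["measured"]
    ratios = None
    if m[("activity", "input")] > 0 and m[("hTR", "input")] > 0:
        ratios = DepletionRatios(
            r_act=min(m[("activity", "flow_through")] / m[("activity", "input")], 1.0),
            r_htr=min(m[("hTR", "flow_through")] / m[("hTR", "input")], 1.0),
        )
    elution = None
    if m[("hTR", "elution")] > 0 and m[("hTERT", "elution")] > 0:
        elution = ElutionStoichiometry(
            htr_per_ul=m[("hTR", "elution")] / elution_volume_ul,
            htert_per_ul=m[("hTERT", "elution")] / elution_volume_ul,
        )
    return {"table": table, "ratios": ratios, "elution": elution, "epsilon": epsilon}


def simulate_blot(
    standard_molecules: list[float],
    sample_molecules: dict[str, float],
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator | None = 0,
    signal_per_molecule: float = 1e-4,
    target: str = "hTR",
    cells_loaded: float | None = None,
    elution_volume_ul: float | None = None,
) -> list[LaneMeasurement]:
    """A blot titration gel: standard lanes plus sample lanes.

    All lanes share the gel's signal scale ``signal_per_molecule``
    (exposure-dependent, differs between gels); lognormal multiplicative
    noise models densitometry scatter.
    """
    rng = _rng(seed)

    def signal(molecules: float) -> float:
        s = signal_per_molecule * molecules
        if noise.blot_lognormal_sigma > 0 and s > 0:
            s *= rng.lognormal(0.0, noise.blot_lognormal_sigma)
        return s

    lanes = [
        LaneMeasurement(
            lane_id=f"std_{i}",
            target=target,
            signal=signal(m),
            role="standard",
            std_molecules=m,
        )
        for i, m in enumerate(standard_molecules)
    ]
    for name, molecules in sample_molecules.items():
        lanes.append(
            LaneMeasurement(
                lane_id=name,
                target=target,
                signal=signal(molecules),
                role="sample",
                cells_loaded=cells_loaded,
                elution_volume_ul=elution_volume_ul,
            )
        )
    return lanes


def simulate_direct_assay(
    truth: GroundTruth,
    recipe: assay_mod.AssayRecipe | None = None,
    duration_min: float | None = None,
    n_telomerase_in_elution: float = 2e7,
    fraction_assayed: float = 0.6,
    lc_cpm: float = 2e4,
    lc_band_fraction: float = 0.9,
    mm_limited: bool = True,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator | None = 0,
    gel_scale_au_per_cpm: float = 5.0,
) -> dict:
    """One direct-assay lane, simulated through the dGTP-pool forward model.

    The per-enzyme velocity is either Michaelis-Menten-limited at the
    recipe's dGTP concentration (default) or the truth's fixed specific
    activity. Expected product radioactivity follows the same arithmetic the
    analysis inverts; counts are Poisson when enabled, and both the product
    ladder and the LC band share an arbitrary gel exposure scale.
    """
    recipe = recipe or assay_mod.AssayRecipe()
    duration = duration_min if duration_min is not None else recipe.duration_min
    rng = _rng(seed)
    pool = assay_mod.dgtp_pool(recipe)
    velocity = (
        kinetics_mod.mm_velocity(pool.total_conc_um, truth.km_um, truth.vmax_nt_min)
        if mm_limited
        else truth.specific_activity_nt_min
    )
    n_enzyme = n_telomerase_in_elution * fraction_assayed
    nt_molecules = velocity * n_enzyme * duration
    nt_pmol = nt_molecules / AVOGADRO * 1e12
    dgmp_pmol = nt_pmol * assay_mod.g_fraction(recipe.repeat_unit)
    expected_cpm = dgmp_pmol * pool.specific_activity_dpm_per_pmol
    prod_cpm = (
        float(rng.poisson(expected_cpm)) if noise.poisson_counting else expected_cpm
    )
    gel = assay_mod.GelQuantification(
        products_signal_au=gel_scale_au_per_cpm * prod_cpm,
        lc_signal_au=gel_scale_au_per_cpm * lc_cpm * lc_band_fraction,
        lc_cpm=lc_cpm,
        lc_band_fraction=lc_band_fraction,
        n_telomerase_molecules=n_telomerase_in_elution,
        fraction_of_elution_assayed=fraction_assayed,
    )
    return {
        "gel": gel,
        "pool": pool,
        "duration_min": duration,
        "true_velocity": velocity,
        "expected_cpm": expected_cpm,
    }


def simulate_dgtp_titration(
    truth: GroundTruth,
    concentrations_um: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 40.0, 80.0),
    rel_noise: float = 0.05,
    n_technical: int = 2,
    replicate: int = 1,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """A dGTP titration of per-enzyme velocities for kinetics fitting.

    Multiplicative lognormal noise with relative scale ``rel_noise`` per
    technical replicate.
    """
    rng = _rng(seed)
    sigma = math.sqrt(math.log(1.0 + rel_noise**2)) if rel_noise > 0 else 0.0
    rows = []
    for s in concentrations_um:
        v_true = kinetics_mod.mm_velocity(s, truth.km_um, truth.vmax_nt_min)
        for tech in range(1, n_technical + 1):
            v = v_true * rng.lognormal(0.0, sigma) if sigma > 0 else v_true
            rows.append(
                {
                    "substrate_uM": s,
                    "velocity": v,
                    "replicate": replicate,
                    "technical_rep": tech,
                }
            )
    return pd.DataFrame(rows)


def with_overexpression(
    truth: GroundTruth, htr_fold: float = 1.0, htert_fold: float = 1.0,
    kd_molecules: float = _BASELINE_KD,
) -> GroundTruth:
    """Re-equilibrate a scenario after overexpressing either subunit.

    Raising either subunit alone increases the assembled pool (mass action),
    which is the mechanism by which single-subunit overexpression raises
    total cellular telomerase activity.
    """
    if htr_fold < 0 or htert_fold < 0:
        raise ValidationError("fold changes must be >= 0")
    a = truth.n_htr_per_cell * htr_fold
    b = truth.n_htert_per_cell * htert_fold
    return replace(
        truth,
        n_htr_per_cell=a,
        n_htert_per_cell=b,
        n_rnp_per_cell=equilibrium_assembly(a, b, kd_molecules),
    )
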