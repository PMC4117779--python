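import numpy as np
import pytest

from telquant import simulate as sim
from telquant.exceptions import EstimationError, ValidationError
from telquant.qpcr import (
    TitrationPoint,
    aggregate_primer_pairs,
    estimate_copies_from_tables,
    fit_titration,
    primer_efficiency,
    relative_quantity,
    spike_ratio,
)


def make_points(s_values, endo, cells=1.0, scale=1.0):
    """Noiseless titration points for a known endogenous amount per reaction."""
    return [
        TitrationPoint(
            std_molecules_added=s,
            relative_quantity_spiked=scale * (endo + s),
            relative_quantity_unspiked=scale * endo,
            cells_per_reaction=cells,
        )
        for s in s_values
    ]


class TestPrimerEfficiency:
    def test_perfect_doubling(self):
        series = [(-i, 20 + 3.321928 * i) for i in range(4)]
        fit = primer_efficiency(series)
        assert fit.efficiency == pytest.approx(2.0, rel=1e-5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_closed_form_3p5(self):
        series = [(-i, 20 + 3.5 * i) for i in range(4)]
        assert primer_efficiency(series).efficiency == pytest.approx(
            10 ** (1 / 3.5), rel=1e-9
        )

    def test_two_points_rejected(self):
        with pytest.raises(EstimationError):
            primer_efficiency([(-1, 23.3), (0, 20)])

    def test_positive_slope_rejected(self):
        with pytest.raises(EstimationError):
            primer_efficiency([(-2, 20), (-1, 23), (0, 26)])


class TestRelativeQuantity:
    def test_symmetry(self):
        a = relative_quantity(20.0, 18.0)
        b = relative_quantity(20.0, 18.0)
        assert a / b == 1.0

    def test_doubling_per_cycle(self):
        base = relative_quantity(20.0, 18.0, 2.0, 2.0)
        up = relative_quantity(19.0, 18.0, 2.0, 2.0)
        assert up / base == pytest.approx(2.0)

    def test_efficiency_corrected(self):
        base = relative_quantity(20.0, 18.0, 1.93, 2.0)
        up = relative_quantity(18.0, 18.0, 1.93, 2.0)
        assert up / base == pytest.approx(1.93**2, rel=1e-9)

    def test_bad_efficiency(self):
        with pytest.raises(ValidationError):
            relative_quantity(20.0, 18.0, eff_target=1.0)


class TestSpikeRatio:
    def test_doubled_quantity_is_unity(self):
        p = TitrationPoint(100, 2.0, 1.0, 1.0)
        assert spike_ratio(p) == pytest.approx(1.0)

    def test_no_spike_is_zero(self):
        p = TitrationPoint(0, 1.5, 1.5, 1.0)
        assert spike_ratio(p) == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [0.25, 0.5, 1.0, 2.0, 4.0])
    def test_noiseless_ratio_equals_spike_multiple(self, k):
        endo = 1300.0
        (p,) = make_points([k * endo], endo)
        assert spike_ratio(p) == pytest.approx(k, rel=1e-12)


class TestFitTitration:
    def test_exact_inversion(self):
        points = make_points([325, 650, 1300, 2600, 5200], endo=1300.0)
        fit = fit_titration(points)
        assert fit.endogenous_per_reaction == pytest.approx(1300.0, rel=1e-9)
        assert fit.endogenous_per_cell == pytest.approx(1300.0, rel=1e-9)
        assert fit.endogenous_per_reaction * fit.slope_per_molecule == pytest.approx(1.0)

    def test_scale_invariance(self):
        """A common rescaling of all relative quantities changes nothing."""
        a = fit_titration(make_points([200, 400, 800], 800.0, scale=1.0))
        b = fit_titration(make_points([200, 400, 800], 800.0, scale=37.5))
        assert a.endogenous_per_cell == pytest.approx(b.endogenous_per_cell, rel=1e-12)

    def test_matches_normal_equations_with_duplicates(self):
        rng = np.random.default_rng(7)
        s = np.array([100.0, 100.0, 200.0, 400.0, 800.0])
        r = s / 500.0 + rng.normal(0, 0.02, size=s.size)
        points = [
            TitrationPoint(si, 1.0 + ri, 1.0, 1.0) for si, ri in zip(s, r)
        ]
        fit = fit_titration(points)
        # brute-force through-origin normal equation
        m = float(np.sum(s * r) / np.sum(s * s))
        assert fit.slope_per_molecule == pytest.approx(m, rel=1e-12)

    def test_free_intercept_reads_ratio_one_crossing(self):
        points = make_points([200, 400, 800, 1600], 800.0)
        fit = fit_titration(points, through_origin=False)
        assert fit.endogenous_per_cell == pytest.approx(800.0, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(EstimationError):
            fit_titration(make_points([100, 200], 500.0))

    def test_all_zero_spikes(self):
        points = [TitrationPoint(0, 1.0, 1.0, 1.0) for _ in range(3)]
        with pytest.raises(EstimationError):
            fit_titration(points)

    def test_no_bracketing_warns(self):
        points = make_points([10, 20, 40], 800.0)  # all R << 1
        fit = fit_titration(points)
        assert any("bracket" in w for w in fit.warnings)


class TestAggregate:
    def test_constant_values(self):
        mean, sd = aggregate_primer_pairs([100.0, 100.0, 100.0])
        assert (mean, sd) == (100.0, 0.0)

    def test_matches_formula(self):
        rng = np.random.default_rng(3)
        vals = list(rng.uniform(500, 2000, size=6))
        mean, sd = aggregate_primer_pairs(vals)
        assert mean == pytest.approx(np.mean(vals))
        assert sd == pytest.approx(np.std(vals, ddof=1))

    def test_singleton_sd_undefined(self):
        mean, sd = aggregate_primer_pairs([880.0])
        assert mean == 880.0 and np.isnan(sd)


class TestEndToEndTables:
    def test_noiseless_identifiability(self):
        """With zero Cq noise the estimator recovers truth to numerical precision."""
        truth = sim.GroundTruth(800.0, 280.0, 240.0)
        wells, design = sim.simulate_qpcr_titration(truth, sim.NOISELESS, seed=0)
        fit = estimate_copies_from_tables(wells, design, "hTR_1", "GAPDH")
        assert fit.endogenous_per_cell == pytest.approx(800.0, rel=1e-6)

    def test_reference_level_irrelevant(self):
        """The estimate does not depend on the reference gene's absolute level."""
        truth = sim.GroundTruth(800.0, 280.0, 240.0)
        fits = []
        for ref_cq in (14.0, 22.0):
            wells, design = sim.simulate_qpcr_titration(
                truth, sim.NOISELESS, seed=0, reference_cq=ref_cq
            )
            fits.append(
                estimate_copies_from_tables(wells, design, "hTR_1", "GAPDH").endogenous_per_cell
            )
        assert fits[0] == pytest.approx(fits[1], rel=1e-9)

    def test_bias_shrinks_with_noise(self):
        """Median recovery error decreases as Cq noise decreases."""
        truth = sim.GroundTruth(800.0, 280.0, 240.0)

        def median_err(sigma, n=40):
            errs = []
            for seed in range(n):
                noise = sim.NoiseModel(sigma_cq=sigma, poisson_counting=False)
                wells, design = sim.simulate_qpcr_titration(truth, noise, seed=seed)
                fit = estimate_copies_from_tables(wells, design, "hTR_1", "GAPDH")
                errs.append(abs(fit.endogenous_per_cell - 800.0) / 800.0)
            return float(np.median(errs))

        assert median_err(0.05) < median_err(0.3)
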