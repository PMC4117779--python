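import numpy as np
import pytest

from telquant import simulate as sim
from telquant.assay import (
    AssayRecipe,
    GelQuantification,
    assay_specific_activity,
    dgtp_pool,
    fold_change_activity,
    g_fraction,
    linearity_check,
    nucleotides_incorporated,
    product_cpm,
    specific_activity,
)
from telquant.exceptions import EstimationError, ValidationError
from telquant.units import AVOGADRO


class TestDgtpPool:
    def test_standard_recipe(self):
        """20 ul of 25 uM cold + 30 uCi hot at 3000 Ci/mmol in 50 ul:
        ~10.2 uM total, SA ~1.306e5 dpm/pmol."""
        pool = dgtp_pool(AssayRecipe())
        assert pool.total_conc_um == pytest.approx(10.2, rel=1e-6)
        assert pool.specific_activity_dpm_per_pmol == pytest.approx(1.306e5, rel=0.001)
        assert pool.total_pmol == pytest.approx(510.0)

    def test_cold_only_limit(self):
        pool = dgtp_pool(AssayRecipe(hot_dgtp_volume_ul=0.0))
        assert pool.total_conc_um == pytest.approx(10.0)
        assert pool.specific_activity_dpm_per_pmol == 0.0

    def test_volume_scaling(self):
        base = dgtp_pool(AssayRecipe())
        doubled = dgtp_pool(AssayRecipe(reaction_volume_ul=100.0))
        assert doubled.total_conc_um == pytest.approx(base.total_conc_um / 2)
        assert doubled.total_pmol == pytest.approx(base.total_pmol)

    def test_pure_hot_arithmetic(self):
        """With no cold dGTP, dGMP pmol equals dpm / (2.22e6 x pmol-per-uCi) exactly."""
        recipe = AssayRecipe(buffer_cold_dgtp_um=0.0)
        pool = dgtp_pool(recipe)
        hot_pmol = 30e-6 / 3000 * 1e9
        assert pool.hot_fraction == 1.0
        assert pool.specific_activity_dpm_per_pmol == pytest.approx(
            30 * 2.22e6 / hot_pmol, rel=1e-12
        )


class TestProductCpm:
    def test_forced_arithmetic(self):
        gel = GelQuantification(100.0, 100.0, lc_cpm=1000.0, lc_band_fraction=0.9)
        assert product_cpm(gel) == pytest.approx(900.0)

    def test_zero_products(self):
        gel = GelQuantification(0.0, 100.0, lc_cpm=1000.0)
        assert product_cpm(gel) == 0.0

    def test_linearity_in_signal(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            s = float(rng.uniform(1, 1e4))
            a = product_cpm(GelQuantification(s, 50.0, lc_cpm=2000.0))
            b = product_cpm(GelQuantification(3 * s, 50.0, lc_cpm=2000.0))
            assert b == pytest.approx(3 * a)

    def test_exposure_scale_cancels(self):
        """Rescaling both gel signals (a different exposure) changes nothing."""
        a = product_cpm(GelQuantification(120.0, 60.0, lc_cpm=1500.0))
        b = product_cpm(GelQuantification(1200.0, 600.0, lc_cpm=1500.0))
        assert a == pytest.approx(b)


class TestNucleotides:
    def test_g_fraction_telomeric_repeat(self):
        assert g_fraction("TTAGGG") == 0.5

    def test_g_free_repeat_rejected(self):
        with pytest.raises(ValidationError):
            g_fraction("TTATTA")

    def test_forced_arithmetic(self):
        pool = dgtp_pool(AssayRecipe())
        sa = pool.specific_activity_dpm_per_pmol
        assert nucleotides_incorporated(sa, pool) == pytest.approx(2.0)


class TestSpecificActivity:
    def test_linearity_in_enzyme(self):
        assert specific_activity(1.0, 1e9, 120.0) == pytest.approx(
            2 * specific_activity(1.0, 2e9, 120.0)
        )

    def test_round_trip_near_saturation(self):
        """Simulated truth ~60 nt/enzyme/min at saturating dGTP recovered within 5%."""
        truth = sim.GroundTruth(800, 280, 240, km_um=17.0, vmax_nt_min=60.0)
        recipe = AssayRecipe(buffer_cold_dgtp_um=2500.0)  # ~1000 uM dGTP, >> Km
        out = sim.simulate_direct_assay(truth, recipe=recipe, seed=1)
        sa = assay_specific_activity(out["gel"], out["pool"], out["duration_min"])
        assert sa == pytest.approx(out["true_velocity"], rel=0.05)
        assert out["true_velocity"] > 58.0

    def test_invariant_to_fraction_assayed(self):
        truth = sim.GroundTruth(800, 280, 240)
        sas = []
        for frac in (0.25, 0.5, 1.0):
            out = sim.simulate_direct_assay(
                truth, fraction_assayed=frac, noise=sim.NOISELESS, seed=0
            )
            sas.append(assay_specific_activity(out["gel"], out["pool"], out["duration_min"]))
        assert sas[0] == pytest.approx(sas[1], rel=1e-9)
        assert sas[1] == pytest.approx(sas[2], rel=1e-9)

    def test_bad_args(self):
        with pytest.raises(ValidationError):
            specific_activity(1.0, 0.0, 120.0)


class TestLinearityCheck:
    def test_perfect_line_passes(self):
        series = [(t, 3.0 * t) for t in (30, 60, 90, 120, 150)]
        res = linearity_check(series, "time_course")
        assert res.passed and res.max_relative_deviation == pytest.approx(0.0)

    def test_saturating_series_flagged(self):
        """A Michaelis-shaped enzyme titration is not linear through the origin."""
        series = [(e, 60.0 * e / (5.0 + e)) for e in (1.0, 2.0, 4.0, 8.0, 16.0)]
        res = linearity_check(series, "enzyme_titration")
        assert not res.passed

    def test_single_outlier_identified(self):
        series = [(1.0, 10.0), (2.0, 20.0), (3.0, 60.0), (4.0, 40.0)]
        res = linearity_check(series)
        assert 2 in res.flagged_indices

    def test_too_few_points(self):
        with pytest.raises(EstimationError):
            linearity_check([(1, 1), (2, 2)])


class TestFoldChange:
    def test_equal_activities(self):
        assert fold_change_activity(10.0, 10.0)[0] == 1.0

    def test_delta_method_sd(self):
        fold, sd = fold_change_activity(10.0, 20.0, sd_a=1.0, sd_b=2.0)
        assert fold == pytest.approx(2.0)
        assert sd == pytest.approx(2.0 * np.sqrt(0.01 + 0.01))

    def test_overexpression_raises_activity(self):
        """Re-equilibrated single-subunit overexpression gives fold > 1."""
        base = sim.preset("hek293t_like")
        for kwargs in ({"htr_fold": 50.0}, {"htert_fold": 10.0}):
            over = sim.with_overexpression(base, **kwargs)
            fold, _ = fold_change_activity(base.n_rnp_per_cell, over.n_rnp_per_cell)
            assert fold > 1.0


def test_nt_invariant_to_gel_exposure():
    pool = dgtp_pool(AssayRecipe())
    a = nucleotides_incorporated(product_cpm(GelQuantification(100, 50, lc_cpm=1e4)), pool)
    b = nucleotides_incorporated(product_cpm(GelQuantification(1000, 500, lc_cpm=1e4)), pool)
    assert a == pytest.approx(b)


def test_total_nt_molecules_scale():
    """2 pmol of nucleotide is ~1.2e12 molecules."""
    assert 2.0 * 1e-12 * AVOGADRO == pytest.approx(1.204e12, rel=1e-3)
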