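import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telquant import simulate as sim
from telquant.exceptions import ValidationError
from telquant.inventory import assembled_monomers_per_cell, tert_per_cell


class TestEquilibriumAssembly:
    def test_tight_binding_limit(self):
        assert sim.equilibrium_assembly(800.0, 280.0, 0.0) == pytest.approx(280.0)
        assert sim.equilibrium_assembly(100.0, 900.0, 0.0) == pytest.approx(100.0)

    def test_symmetric_closed_form(self):
        """A = B = Kd gives x = (3 - sqrt(5))/2 x A."""
        for a in (1.0, 240.0, 1e6):
            expected = (3 - math.sqrt(5)) / 2 * a
            assert sim.equilibrium_assembly(a, a, a) == pytest.approx(expected, rel=1e-12)

    def test_matches_numeric_root(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            a, b, kd = rng.uniform(1, 1e4, size=3)
            x = sim.equilibrium_assembly(a, b, kd)
            assert x**2 - (a + b + kd) * x + a * b == pytest.approx(0.0, abs=1e-4 * a * b)
            assert 0 <= x <= min(a, b)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=1.0, max_value=1e6),
        st.floats(min_value=1.0, max_value=1e6),
        st.floats(min_value=1.0, max_value=1e6),
        st.floats(min_value=1.1, max_value=10.0),
    )
    def test_monotone_in_either_subunit(self, a, b, kd, fold):
        # strictly monotone for Kd > 0; at Kd = 0 the limiting subunit caps x
        x = sim.equilibrium_assembly(a, b, kd)
        assert sim.equilibrium_assembly(fold * a, b, kd) > x
        assert sim.equilibrium_assembly(a, fold * b, kd) > x

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            sim.equilibrium_assembly(-1.0, 1.0, 1.0)


class TestIpSimulation:
    def test_full_efficiency_noiseless_closed_form(self):
        truth = sim.GroundTruth(800.0, 280.0, 240.0)
        out = sim.simulate_ip(truth, epsilon=1.0, noise=sim.NOISELESS)
        assert out["ratios"].r_act == pytest.approx(0.0)
        assert out["ratios"].r_htr == pytest.approx(1 - 240.0 / 800.0)
        est = assembled_monomers_per_cell(800.0, out["ratios"])
        assert est.monomers_per_cell == pytest.approx(240.0, rel=1e-12)

    def test_efficiency_invariance(self):
        """The estimator returns the same truth at every pull-down efficiency."""
        truth = sim.GroundTruth(800.0, 280.0, 240.0)
        estimates = []
        for eps in np.arange(0.1, 0.95, 0.1):
            out = sim.simulate_ip(truth, epsilon=float(eps), noise=sim.NOISELESS)
            estimates.append(
                assembled_monomers_per_cell(800.0, out["ratios"]).monomers_per_cell
            )
        assert np.ptp(estimates) == pytest.approx(0.0, abs=1e-9)

    def test_conservation_pre_noise(self):
        """Input = flow-through + elution exactly in the expected columns."""
        truth = sim.GroundTruth(1300.0, 500.0, 240.0)
        out = sim.simulate_ip(truth, epsilon=0.37, noise=sim.NoiseModel(), seed=5)
        t = out["table"].pivot(index="species", columns="fraction", values="expected")
        assert np.allclose(t["input"], t["flow_through"] + t["elution"])

    def test_free_tert_pulldown_mode(self):
        """With free hTERT captured too, elution stoichiometry reports total hTERT."""
        truth = sim.GroundTruth(1300.0, 500.0, 240.0)
        out = sim.simulate_ip(truth, epsilon=0.5, noise=sim.NOISELESS, pull_free_tert=True)
        est = tert_per_cell(truth.n_rnp_per_cell, out["elution"])
        assert est == pytest.approx(500.0, rel=1e-9)
        # without the mode, elution hTERT:hTR is 1:1 and reports RNP only
        out2 = sim.simulate_ip(truth, epsilon=0.5, noise=sim.NOISELESS)
        assert tert_per_cell(truth.n_rnp_per_cell, out2["elution"]) == pytest.approx(240.0)

    def test_unbiased_under_poisson(self):
        truth = sim.GroundTruth(800.0, 280.0, 240.0)
        estimates = []
        for seed in range(60):
            out = sim.simulate_ip(truth, epsilon=0.5, noise=sim.NoiseModel(), seed=seed)
            estimates.append(
                assembled_monomers_per_cell(800.0, out["ratios"]).monomers_per_cell
            )
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 240.0) <= max(3 * se, 1.0)

    def test_zero_rnp_scenario(self):
        out = sim.simulate_ip(sim.preset("va13_like"), epsilon=0.5, noise=sim.NOISELESS)
        assert out["ratios"] is None and out["elution"] is None


class TestDeterminism:
    def test_qpcr_tables_identical_under_fixed_seed(self):
        truth = sim.preset("hek293t_like")
        a_wells, a_design = sim.simulate_qpcr_titration(truth, seed=42)
        b_wells, b_design = sim.simulate_qpcr_titration(truth, seed=42)
        pd.testing.assert_frame_equal(a_wells, b_wells)
        pd.testing.assert_frame_equal(a_design, b_design)

    def test_ip_and_blot_deterministic(self):
        truth = sim.preset("hela_like")
        a = sim.simulate_ip(truth, 0.4, sim.NoiseModel(), seed=7)
        b = sim.simulate_ip(truth, 0.4, sim.NoiseModel(), seed=7)
        pd.testing.assert_frame_equal(a["table"], b["table"])
        la = sim.simulate_blot([1e6, 2e6], {"s": 1.5e6}, seed=3, cells_loaded=1e3)
        lb = sim.simulate_blot([1e6, 2e6], {"s": 1.5e6}, seed=3, cells_loaded=1e3)
        assert [l.signal for l in la] == [l.signal for l in lb]

    def test_different_seeds_differ(self):
        truth = sim.preset("hek293t_like")
        a, _ = sim.simulate_qpcr_titration(truth, seed=1)
        b, _ = sim.simulate_qpcr_titration(truth, seed=2)
        assert not a["cq"].equals(b["cq"])


class TestPresets:
    def test_known_scenarios(self):
        hek = sim.preset("hek293t_like")
        assert (hek.n_htr_per_cell, hek.n_htert_per_cell, hek.n_rnp_per_cell) == (800, 280, 240)
        assert sim.preset("va13_like").n_htr_per_cell == 0.0
        sup = sim.preset("super_telomerase")
        assert sup.n_htr_per_cell == 48000.0
        assert sup.n_rnp_per_cell > 10 * hek.n_rnp_per_cell

    def test_unknown_preset(self):
        with pytest.raises(ValidationError):
            sim.preset("k562_like")

    def test_truth_invariants(self):
        with pytest.raises(ValidationError):
            sim.GroundTruth(100.0, 100.0, 200.0)


class TestOverexpression:
    def test_single_subunit_overexpression_raises_assembly(self):
        base = sim.preset("hek293t_like")
        more_rna = sim.with_overexpression(base, htr_fold=50.0)
        more_protein = sim.with_overexpression(base, htert_fold=10.0)
        assert more_rna.n_rnp_per_cell > base.n_rnp_per_cell
        assert more_protein.n_rnp_per_cell > base.n_rnp_per_cell
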