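"""Energy-gap linear-response free-energy curves and parameter extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bc1sox import linres, synth
from bc1sox.thermo import Thermo


class TestGapArithmetic:
    def test_elementwise_difference(self):
        np.testing.assert_allclose(linres.gap_from_energies([10.0], [30.0]), [-20.0])
        np.testing.assert_allclose(linres.gap_from_energies([1, 2], [0, 0]), [1, 2])

    def test_identical_series_give_zero(self):
        u = np.arange(5.0)
        assert np.all(linres.gap_from_energies(u, u) == 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            linres.gap_from_energies([1, 2], [1])


class TestSummaries:
    def test_two_point_moments(self):
        s = linres.summarize_gaps(linres.GapSampleSet("reactant", [-1.0, 1.0]))
        assert s.mean == 0.0
        assert s.sd == pytest.approx(np.sqrt(2))
        assert s.skewness == 0.0

    def test_symmetric_sample_has_zero_skewness(self):
        x = np.concatenate([np.linspace(-3, 3, 101)])
        assert linres.summarize_gaps(
            linres.GapSampleSet("reactant", x)
        ).skewness == pytest.approx(0.0, abs=1e-12)

    def test_large_normal_sample_skewness_within_asymptotic_band(self):
        rng = np.random.default_rng(0)
        n = 100_000
        s = linres.summarize_gaps(linres.GapSampleSet("reactant", rng.normal(size=n)))
        assert abs(s.skewness) < 3 * np.sqrt(6 / n)

    def test_skewed_sample_warns(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="skew"):
            linres.summarize_gaps(
                linres.GapSampleSet("product", rng.exponential(size=5000))
            )


class TestEmpiricalCurve:
    def test_gaussian_curve_matches_parabola_within_two_sigma(self, thermo300):
        reactant, _ = synth.gen_gap_samples(
            synth.GapGenConfig(delta_g0_true=-20.0, lambda_true=83.87,
                               n_samples=100_000, seed=17)
        )
        centers, g = linres.empirical_free_energy_curve(reactant, thermo300)
        summary = linres.summarize_gaps(reactant)
        parabola = linres.parabola_from_summary(summary, thermo300)
        mask = np.abs(centers - summary.mean) < 2 * summary.sd
        assert np.max(np.abs(g[mask] - parabola.g(centers[mask]))) < 0.5

    def test_uniform_samples_give_flat_curve(self, thermo300):
        rng = np.random.default_rng(2)
        gap_set = linres.GapSampleSet("reactant", rng.uniform(0, 10, 50_000))
        centers, g = linres.empirical_free_energy_curve(gap_set, thermo300, bins=20)
        interior = g[2:-2]
        assert np.ptp(interior) < 0.05

    def test_doubling_counts_leaves_curve_unchanged(self, thermo300):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        c1, g1 = linres.empirical_free_energy_curve(
            linres.GapSampleSet("reactant", x), thermo300, bins=15
        )
        c2, g2 = linres.empirical_free_energy_curve(
            linres.GapSampleSet("reactant", np.concatenate([x, x])), thermo300, bins=15
        )
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_degenerate_sample_rejected(self, thermo300):
        with pytest.raises(ValueError):
            linres.empirical_free_energy_curve(
                linres.GapSampleSet("reactant", np.ones(100)), thermo300
            )


class TestParabola:
    def test_curvature_formula(self, thermo300):
        p = linres.parabola_from_summary(
            linres.GaussianSummary(0.0, 10.0, 0.0, 100), thermo300
        )
        assert p.a == pytest.approx(0.0029808)

    def test_wide_distribution_flattens(self, thermo300):
        p = linres.parabola_from_summary(
            linres.GaussianSummary(0.0, 1e6, 0.0, 100), thermo300
        )
        assert p.a < 1e-12

    def test_vertex_value_is_offset(self):
        p = linres.Parabola(0.5, 3.0, offset=1.25)
        assert p.g(3.0) == 1.25


class TestAlignment:
    def test_equal_variance_closed_form(self, thermo300):
        # sigma = 10, vertices at dG0 +/- Lambda: the rounded inputs
        # reproduce dG0 = -20 and Lambda = 83.87 to ~1e-4
        a = thermo300.kbt / (2 * 10.0**2)
        diagram = linres.align_and_extract(
            linres.Parabola(a, 63.87), linres.Parabola(a, -103.87)
        )
        assert diagram.delta_g0 == pytest.approx(-20.0, abs=1e-3)
        assert diagram.lambda_p == pytest.approx(83.87, abs=1e-3)
        assert diagram.lambda_r == pytest.approx(83.87, abs=1e-3)

    def test_identical_parabolas_are_degenerate(self):
        with pytest.warns(UserWarning):
            diagram = linres.align_and_extract(
                linres.Parabola(0.01, 5.0), linres.Parabola(0.01, 5.0)
            )
        assert diagram.delta_g0 == pytest.approx(0.0)
        assert diagram.lambda_p == 0.0

    def test_activationless_case_intersects_at_product_vertex(self, thermo300):
        """When dG0 = Lambda_r the crossing point (always dU = 0 after
        alignment) coincides with the product-state equilibrium — the
        activationless configuration of the reverse reaction, whose
        Lambda_p equals minus its driving force."""
        lam = 83.87
        sigma = np.sqrt(2 * lam * thermo300.kbt)
        a = thermo300.kbt / (2 * sigma**2)
        diagram = linres.align_and_extract(
            linres.Parabola(a, 2 * lam), linres.Parabola(a, 0.0)
        )
        assert diagram.product.vertex == 0.0
        assert diagram.delta_g0 == pytest.approx(diagram.lambda_r, rel=1e-9)
        v_p = diagram.product.vertex
        assert diagram.reactant.g(v_p) == pytest.approx(diagram.product.g(v_p), abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        ar=st.floats(1e-4, 1.0), ap=st.floats(1e-4, 1.0),
        vr=st.floats(-200, 200), vp=st.floats(-200, 200),
    )
    def test_alignment_invariant_g_equal_at_zero(self, ar, ap, vr, vp):
        d = linres.align_and_extract(linres.Parabola(ar, vr), linres.Parabola(ap, vp))
        assert d.reactant.g(0.0) == pytest.approx(d.product.g(0.0), abs=1e-6)


class TestFullLinearResponse:
    CFG = dict(delta_g0_true=-20.0, lambda_true=83.87, n_samples=100_000, seed=23)

    def test_parameter_recovery_equal_variance(self, thermo300):
        reactant, product = synth.gen_gap_samples(synth.GapGenConfig(**self.CFG))
        diagram = linres.full_linear_response(reactant, product, thermo300)
        # SE of dG0 ~ sigma/(2 sqrt(n)) per state mean; generous 3x band
        se = reactant.meta["sigma_reactant"] / np.sqrt(self.CFG["n_samples"])
        assert diagram.delta_g0 == pytest.approx(-20.0, abs=3 * se)
        assert diagram.lambda_p == pytest.approx(83.87, rel=0.02)
        assert diagram.lambda_r == pytest.approx(83.87, rel=0.02)

    def test_unequal_variance_splits_the_reorganization_energies(self, thermo300):
        reactant, product = synth.gen_gap_samples(
            synth.GapGenConfig(**{**self.CFG, "sigma_ratio": 1.2})
        )
        diagram = linres.full_linear_response(reactant, product, thermo300)
        assert diagram.lambda_p > 0 and diagram.lambda_r > 0
        assert diagram.lambda_p != pytest.approx(diagram.lambda_r, rel=0.05)
        # smaller curvature (wider product distribution) means lambda_p < lambda_r
        assert diagram.lambda_p < diagram.lambda_r

    def test_swapping_states_negates_the_driving_force(self, thermo300):
        reactant, product = synth.gen_gap_samples(synth.GapGenConfig(**self.CFG))
        forward = linres.full_linear_response(reactant, product, thermo300)
        swapped = linres.full_linear_response(
            linres.GapSampleSet("reactant", product.samples),
            linres.GapSampleSet("product", reactant.samples),
            thermo300,
        )
        assert swapped.delta_g0 == pytest.approx(-forward.delta_g0, abs=1e-9)

    def test_curves_attached_for_sampled_ranges(self, thermo300):
        reactant, product = synth.gen_gap_samples(
            synth.GapGenConfig(**{**self.CFG, "n_samples": 5000})
        )
        diagram = linres.full_linear_response(reactant, product, thermo300)
        assert diagram.reactant_curve is not None
        assert diagram.product_curve is not None
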