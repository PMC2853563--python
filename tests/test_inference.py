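"""Goodness-of-fit, assumption checks, and crossing-probability curves."""

import numpy as np
import pytest

from rhomboclone.clone_data import CategoryCounts
from rhomboclone.null_model import CategoryProbabilities, LognormalRadiusModel
from rhomboclone.inference import (
    binned_crossing_fraction,
    chisq_gof,
    compare_curves,
    ks_lognormal_radii,
    ks_uniform_positions,
    size_position_correlation,
    smooth_crossing_probability,
    theoretical_curve,
)
from rhomboclone.synthetic_data import SimulationConfig, simulate_restricted_clones


class TestChisqGof:
    def test_published_trinomial_table(self):
        """The published 116-clone table: observed (respect 34, cross 12,
        middle 70) against chance probabilities (0.22, 0.57, 0.21)."""
        result = chisq_gof(
            CategoryCounts(n_cross=12, n_respect=34, n_middle=70),
            CategoryProbabilities(p_cross=0.57, p_respect=0.22, p_middle=0.21),
        )
        # canonical order (cross, respect, middle)
        assert np.round(result.expected, 1).tolist() == [66.1, 25.5, 24.4]
        assert np.round(result.discrepancy, 1).tolist() == [44.3, 2.8, 85.5]
        assert round(result.chi2, 1) == 132.6
        assert result.df == 2
        assert result.p_value < 1e-15
        assert result.p_label() == "p < 1e-15"

    def test_internal_consistency(self):
        result = chisq_gof(
            CategoryCounts(5, 7, 11), CategoryProbabilities(0.3, 0.3, 0.4)
        )
        assert result.chi2 == pytest.approx(result.discrepancy.sum())
        assert result.expected.sum() == pytest.approx(23)

    @pytest.mark.parametrize(
        "counts,probs",
        [
            ((2, 1, 1), (0.5, 0.25, 0.25)),
            ((10, 10, 10), (1 / 3, 1 / 3, 1 / 3)),
        ],
    )
    def test_perfect_fit(self, counts, probs):
        result = chisq_gof(CategoryCounts(*counts), CategoryProbabilities(*probs))
        assert result.chi2 == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_zero_expected_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            chisq_gof(CategoryCounts(1, 1, 1), CategoryProbabilities(1.0, 0.0, 0.0))


class TestKsChecks:
    def test_uniform_level(self):
        """Under uniform positions the KS test keeps its nominal level:
        p > 0.05 in at least 94 of 100 seeded replicates."""
        rng = np.random.default_rng(11)
        passed = sum(
            ks_uniform_positions(rng.uniform(size=1000)).p_value > 0.05
            for _ in range(100)
        )
        assert passed >= 94

    def test_concentrated_positions_rejected(self):
        assert ks_uniform_positions([0.5] * 50).p_value < 1e-6

    def test_positions_out_of_range(self):
        with pytest.raises(ValueError):
            ks_uniform_positions([0.2, 0.3, 1.5, 0.1, 0.4])

    def test_lognormal_level(self, model):
        """p > 0.05 in at least 90 of 100 replicates with true parameters."""
        rng = np.random.default_rng(12)
        passed = sum(
            ks_lognormal_radii(
                rng.lognormal(model.mu, model.sigma, 1000), model
            ).p_value
            > 0.05
            for _ in range(100)
        )
        assert passed >= 90

    def test_constant_radii_rejected(self, model):
        assert ks_lognormal_radii([0.3] * 100, model).p_value < 1e-6

    def test_wrong_distribution_rejected(self, model):
        rng = np.random.default_rng(13)
        radii = rng.uniform(0.4, 0.6, 1000)
        assert ks_lognormal_radii(radii, model).p_value < 0.01


class TestCorrelation:
    def test_identity(self):
        x = np.linspace(0.1, 0.9, 50)
        assert size_position_correlation(x, x) == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.linspace(0.0, 1.0, 50)
        assert size_position_correlation(x, 0.5 - 0.4 * x) == pytest.approx(-1.0)

    def test_independent_null(self):
        rng = np.random.default_rng(14)
        n = 10_000
        x = rng.uniform(size=n)
        r = rng.lognormal(-1.34, 0.64, n)
        assert abs(size_position_correlation(x, r)) < 3 / np.sqrt(n)


class TestBinnedCurve:
    def test_half_crossing_bin(self):
        curve = binned_crossing_fraction([0.02, 0.08], [True, False])
        assert curve.p[0] == pytest.approx(0.5)
        assert np.all(np.isnan(curve.p[1:]))  # empty bins are missing, not zero

    def test_all_crossing_flat_at_one(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(size=200)
        curve = binned_crossing_fraction(x, np.ones(200, bool))
        assert np.nanmin(curve.p) == 1.0

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            binned_crossing_fraction([0.5], [True], bin_width=0.3)

    def test_null_bins_track_theory(self, model, null_table_5000):
        """Null-sample bin fractions lie within 3 binomial SE of their exact
        success probability, the average of L over each bin."""
        from scipy import integrate

        x = null_table_5000["x"].to_numpy()
        r = null_table_5000["r"].to_numpy()
        y = r > np.minimum(x, 1 - x)
        curve = binned_crossing_fraction(x, y)
        edges = curve.bin_edges
        L_bin = np.array(
            [
                integrate.quad(model.crossing_probability, lo, hi)[0] / (hi - lo)
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        counts = np.histogram(x, bins=edges)[0]
        se = np.sqrt(L_bin * (1 - L_bin) / counts)
        assert np.all(np.abs(curve.p - L_bin) < 3 * se)


class TestSmoothedCurve:
    def test_single_class_degenerate(self):
        x = np.linspace(0.05, 0.95, 40)
        with pytest.warns(UserWarning, match="one outcome class"):
            curve = smooth_crossing_probability(x, np.zeros(40, bool))
        assert np.allclose(curve.p, 0.0)

    def test_too_few_clones(self):
        with pytest.raises(ValueError, match="at least 20"):
            smooth_crossing_probability([0.1] * 10, [True] * 10)

    def test_circular_endpoints_match(self, null_table_5000):
        x = null_table_5000["x"].to_numpy()[:2000]
        r = null_table_5000["r"].to_numpy()[:2000]
        y = r > np.minimum(x, 1 - x)
        curve = smooth_crossing_probability(x, y, circular=True)
        assert curve.p[0] == curve.p[-1]  # exact period-1 identification
        assert np.all((curve.p >= 0) & (curve.p <= 1))

    def test_fully_restricted_curve_near_zero(self, calibrated_delta):
        """With restriction strength 1 no clone crosses, so the fitted
        crossing curve collapses to ~0 everywhere."""
        table = simulate_restricted_clones(
            SimulationConfig(n_clones=1000, beta=1.0, seed=3)
        )
        x = table["x"].to_numpy()
        y = table["r"].to_numpy() > np.minimum(x, 1 - x)
        assert not y.any()
        with pytest.warns(UserWarning):
            curve = smooth_crossing_probability(x, y)
        assert np.all(curve.p < 0.05)


class TestCompareCurves:
    def test_identical_curves(self, model):
        theo = theoretical_curve(model)
        cmp = compare_curves(theo, theo)
        assert cmp.max_abs == 0.0
        assert cmp.mean_abs == 0.0
        assert cmp.frac_below == 1.0

    def test_restricted_lies_below_theory(self, model, calibrated_delta):
        """Under boundary restriction the empirical crossing curve falls at
        or below the no-restriction prediction on nearly all of the grid."""
        table = simulate_restricted_clones(
            SimulationConfig(n_clones=5000, beta=0.8, seed=4)
        )
        x = table["x"].to_numpy()
        y = table["r"].to_numpy() > np.minimum(x, 1 - x)
        smoothed = smooth_crossing_probability(x, y)
        cmp = compare_curves(smoothed, theoretical_curve(model))
        assert cmp.frac_below >= 0.9
        assert cmp.max_abs > 0.2  # restriction signal, not noise
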