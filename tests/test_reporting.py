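"""HDI, tail-probability, contrast and stacked-predictive checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldsirt import contrast_prob, hdi, posterior_prob_below, stacked_predictive, summary_table


class TestHdi:
    def test_degenerate_samples_zero_width(self):
        lo, hi = hdi(np.full(100, 1.7), 0.9)
        assert lo == hi == 1.7

    def test_normal_central_interval_oracle(self):
        # 1e6 draws keep the HDI endpoints' Monte-Carlo noise ~0.01
        rng = np.random.default_rng(1)
        lo, hi = hdi(rng.normal(size=1_000_000), 0.90)
        assert lo == pytest.approx(-1.645, abs=0.02)
        assert hi == pytest.approx(1.645, abs=0.02)

    def test_exponential_interval_starts_at_minimum(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(size=50_000)
        lo, hi = hdi(x, 0.66)
        assert lo == x.min()

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(30.0), 1.2)

    def test_matches_arviz(self):
        import arviz as az

        rng = np.random.default_rng(2)
        x = rng.gamma(3.0, size=20_000)
        lo, hi = hdi(x, 0.9)
        ref = az.hdi(x, hdi_prob=0.9)
        assert lo == pytest.approx(float(ref[0]), abs=0.02)
        assert hi == pytest.approx(float(ref[1]), abs=0.02)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_mass_nesting(self, seed):
        """The 66% HDI lies inside the 90% HDI for unimodal samples."""
        x = np.random.default_rng(seed).normal(size=500)
        lo66, hi66 = hdi(x, 0.66)
        lo90, hi90 = hdi(x, 0.90)
        assert lo90 <= lo66 and hi66 <= hi90


class TestProbBelow:
    def test_all_below(self):
        assert posterior_prob_below(np.full(50, -0.5), -0.1) == 1.0

    def test_symmetric_about_threshold(self):
        x = -0.1 + np.concatenate([np.linspace(0.01, 1, 50), -np.linspace(0.01, 1, 50)])
        assert posterior_prob_below(x, -0.1) == pytest.approx(0.5)

    def test_ties_count_as_not_below(self):
        assert posterior_prob_below(np.array([-0.1, -0.2]), -0.1) == 0.5

    @given(st.integers(0, 10_000), st.floats(-2, 2))
    @settings(max_examples=25, deadline=None)
    def test_reflection_identity(self, seed, t):
        """P(X < t) + P(-X < -t) = 1 for continuous samples without ties."""
        x = np.random.default_rng(seed).normal(size=200)
        assert posterior_prob_below(x, t) + posterior_prob_below(-x, -t) == pytest.approx(1.0)


class TestContrast:
    def test_identical_draws(self):
        x = np.random.default_rng(0).normal(size=100)
        mean, sd, p = contrast_prob(x, x)
        assert mean == 0.0 and sd == 0.0 and p == 0.0

    def test_unit_shift(self):
        x = np.random.default_rng(1).normal(size=100)
        mean, sd, p = contrast_prob(x, x + 1.0)
        assert mean == pytest.approx(-1.0)
        assert p == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            contrast_prob(np.zeros(3), np.zeros(4))


class TestStackedPredictive:
    def test_degenerate_weights_equal_single_model(self, small_fits):
        _, fits = small_fits
        grid = np.linspace(-2, 2, 5)
        sub = {v: fits[v] for v in ("discrepancy", "adolescent")}
        stacked = stacked_predictive(sub, np.array([1.0, 0.0]), "mother", grid, seed=0)
        single = stacked_predictive({"discrepancy": fits["discrepancy"]},
                                    np.array([1.0]), "mother", grid, seed=0)
        assert np.allclose(stacked.probs, single.probs, atol=1e-12)

    def test_category_frequencies_normalized(self, small_fits):
        _, fits = small_fits
        sub = {v: fits[v] for v in ("discrepancy", "adolescent")}
        curve = stacked_predictive(sub, np.array([0.7, 0.3]), "mother",
                                   np.linspace(-2, 2, 7), seed=1)
        assert np.allclose(curve.probs.sum(axis=1), 1.0, atol=1e-10)

    def test_clinical_category_decreases_with_discrepancy(self, small_fits):
        """Posterior-mean P(clinical hopelessness) falls as the parent
        reports increasingly more conflict than the adolescent (beta < 0)."""
        _, fits = small_fits
        curve = stacked_predictive({"discrepancy": fits["discrepancy"]},
                                   np.array([1.0]), "mother",
                                   np.linspace(-2, 2, 9), seed=2)
        p3 = curve.probs[:, 2]
        assert np.all(np.diff(p3) < 0)

    def test_empty_grid_rejected(self, small_fits):
        _, fits = small_fits
        with pytest.raises(ValueError):
            stacked_predictive({"discrepancy": fits["discrepancy"]},
                               np.array([1.0]), "mother", [], seed=0)

    def test_invalid_weights_rejected(self, small_fits):
        _, fits = small_fits
        with pytest.raises(ValueError):
            stacked_predictive({"discrepancy": fits["discrepancy"]},
                               np.array([0.7]), "mother", [0.0], seed=0)


class TestSummaryTable:
    def test_schema_and_sanity(self, small_fits):
        _, fits = small_fits
        tab = summary_table(fits["discrepancy"])
        expected_cols = ["parameter", "mean", "sd", "median", "hdi66_lower",
                         "hdi66_upper", "hdi90_lower", "hdi90_upper", "ess"]
        assert list(tab.columns) == expected_cols
        assert (tab.hdi66_lower <= tab.hdi66_upper).all()
        assert (tab.hdi90_lower <= tab.hdi66_lower).all()
        assert (tab.hdi66_upper <= tab.hdi90_upper).all()
        assert not any(tab.parameter.str.startswith(("theta", "delta")))

    def test_standard_normal_draws(self):
        from ldsirt.inference import PosteriorDraws

        rng = np.random.default_rng(3)
        fit = PosteriorDraws(params={"x": rng.normal(size=(2, 20_000))})
        row = summary_table(fit, parameters=["x"]).iloc[0]
        assert row["mean"] == pytest.approx(0.0, abs=0.02)
        assert row["median"] == pytest.approx(0.0, abs=0.02)
        assert row["sd"] == pytest.approx(1.0, abs=0.02)

    def test_constant_parameter(self):
        from ldsirt.inference import PosteriorDraws

        fit = PosteriorDraws(params={"x": np.full((2, 100), 2.5)})
        row = summary_table(fit, parameters=["x"]).iloc[0]
        assert row["sd"] == 0.0
        assert row["hdi90_lower"] == row["hdi90_upper"] == 2.5
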