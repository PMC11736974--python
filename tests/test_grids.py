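"""Hazard-grid conversions: h_t -> H_t -> F_t -> p_t and their inverses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npsample import (
    CdfGrid,
    CumulativeHazardGrid,
    HazardGrid,
    cdf_from_cumulative,
    continuous_cumulative_from_hazard_function,
    cumulative_from_interval_hazards,
    interval_hazards_from_continuous_cumulative,
    pmf_from_cdf,
    pmf_from_hazards,
    refine,
    rescale_hazards,
)


class TestCumulativeFromIntervalHazards:
    @pytest.mark.parametrize("hazards, delta_t, expected", [
        ([0, 0, 0], 1.0, [0, 0, 0, 0]),
        ([0.1] * 10, 1.0, None),  # constant hazard: H_10 = 1.0
        ([0.2, 0.4], 0.5, [0, 0.1, 0.3]),
    ])
    def test_running_sum_with_delta_t_scaling(self, hazards, delta_t, expected):
        cum = cumulative_from_interval_hazards(HazardGrid(delta_t, hazards))
        assert len(cum) == len(hazards) + 1
        assert cum.values[0] == 0
        if expected is None:
            assert cum.values[-1] == pytest.approx(1.0, abs=1e-15)
        else:
            np.testing.assert_allclose(cum.values, expected, atol=1e-15)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError, match="nonneg"):
            HazardGrid(1.0, [0.1, -0.2])

    def test_non_finite_hazard_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            HazardGrid(1.0, [0.1, np.inf])


class TestCdfFromCumulative:
    @pytest.mark.parametrize("H, expected", [
        ([0.0], [0.0]),
        ([0.0, np.log(2)], [0.0, 0.5]),
        ([0.0, 1.0], [0.0, 1 - np.exp(-1)]),
    ])
    def test_one_minus_exp(self, H, expected):
        cdf = cdf_from_cumulative(CumulativeHazardGrid(1.0, H))
        np.testing.assert_allclose(cdf.values, expected, atol=1e-15)

    def test_decreasing_input_rejected(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            CumulativeHazardGrid(1.0, [0.0, 0.5, 0.2])

    @given(st.lists(st.floats(0, 2), min_size=1, max_size=30), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_cumulative_hazard(self, h, data):
        """Pointwise larger cumulative hazard gives pointwise larger CDF."""
        bump = data.draw(st.lists(st.floats(0, 1), min_size=len(h), max_size=len(h)))
        lo = cumulative_from_interval_hazards(HazardGrid(1.0, h))
        hi = cumulative_from_interval_hazards(
            HazardGrid(1.0, np.asarray(h) + np.asarray(bump)))
        assert np.all(cdf_from_cumulative(hi).values
                      >= cdf_from_cumulative(lo).values - 1e-15)


class TestIntervalHazardsFromContinuousCumulative:
    def test_linear_cumulative_gives_constant_hazard(self):
        grid = interval_hazards_from_continuous_cumulative(
            lambda t: 0.1 * t, delta_t=1.0, horizon=10)
        np.testing.assert_allclose(grid.hazards, 0.1, atol=1e-14)

    def test_quadratic_finite_difference(self):
        grid = interval_hazards_from_continuous_cumulative(
            lambda t: 0.01 * t ** 2, delta_t=1.0, horizon=5)
        np.testing.assert_allclose(grid.hazards[:2], [0.01, 0.03], atol=1e-14)

    def test_per_unit_scale_preserved_on_fine_grid(self):
        grid = interval_hazards_from_continuous_cumulative(
            lambda t: 0.1 * t, delta_t=1 / 12, horizon=2)
        np.testing.assert_allclose(grid.hazards, 0.1, atol=1e-12)

    def test_decreasing_cumulative_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            interval_hazards_from_continuous_cumulative(
                lambda t: -t, delta_t=1.0, horizon=3)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_reproduces_cumulative_at_grid_points(self, h):
        """Finite differencing then re-accumulating is the identity on H."""
        base = cumulative_from_interval_hazards(HazardGrid(0.5, h))
        Hfun = lambda t: np.interp(t, 0.5 * np.arange(len(base)), base.values)
        grid = interval_hazards_from_continuous_cumulative(
            Hfun, delta_t=0.5, horizon=0.5 * len(h))
        again = cumulative_from_interval_hazards(grid)
        np.testing.assert_allclose(again.values, base.values, atol=1e-10)


class TestContinuousCumulativeFromHazardFunction:
    def test_constant_hazard_exact(self):
        cum = continuous_cumulative_from_hazard_function(
            lambda t: 0.25 * np.ones_like(t), delta_t=1.0, horizon=8)
        np.testing.assert_allclose(cum.values, 0.25 * np.arange(9), atol=1e-10)

    def test_linear_hazard_quadratic_integral(self):
        cum = continuous_cumulative_from_hazard_function(
            lambda t: 0.02 * t, delta_t=1.0, horizon=10)
        assert cum.values[-1] == pytest.approx(1.0, abs=1e-9)

    def test_gompertz_closed_form_integral(self):
        cum = continuous_cumulative_from_hazard_function(
            lambda t: 0.001 * np.exp(0.1 * t), delta_t=1.0, horizon=10)
        assert cum.values[-1] == pytest.approx(0.001 * (np.e - 1) / 0.1, rel=1e-8)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            continuous_cumulative_from_hazard_function(
                lambda t: np.asarray(t) - 5.0, delta_t=1.0, horizon=10)


class TestPmfFromCdf:
    @pytest.mark.parametrize("F, probs, residual", [
        ([0, 0.5, 1.0], [0.5, 0.5], 0.0),
        ([0, 0.3], [0.3], 0.7),
    ])
    def test_differences_and_residual(self, F, probs, residual):
        pmf = pmf_from_cdf(CdfGrid(1.0, F))
        np.testing.assert_allclose(pmf.probs, probs, atol=1e-15)
        assert pmf.residual == pytest.approx(residual, abs=1e-15)

    def test_exponential_first_interval_probability(self):
        grid = HazardGrid(1.0, [0.1] * 50)
        pmf = pmf_from_hazards(grid)
        assert pmf.probs[0] == pytest.approx(1 - np.exp(-0.1), abs=1e-12)

    @given(st.lists(st.floats(0, 3), min_size=1, max_size=60),
           st.floats(0.01, 10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_normalization_with_residual(self, h, delta_t):
        """p_t and the beyond-horizon residual always sum to exactly 1."""
        pmf = pmf_from_hazards(HazardGrid(delta_t, h))
        assert abs(pmf.probs.sum() + pmf.residual - 1.0) <= 1e-12
        assert np.all(pmf.probs >= 0) and pmf.residual >= 0

    def test_constant_hazard_pmf_is_geometric(self):
        """For constant hazard the interval pmf is geometric in closed form."""
        lam, dt = 0.3, 0.5
        pmf = pmf_from_hazards(HazardGrid(dt, [lam] * 40))
        t = np.arange(40)
        expected = np.exp(-lam * dt * t) * (1 - np.exp(-lam * dt))
        np.testing.assert_allclose(pmf.probs, expected, atol=1e-12)

    def test_renormalized_drops_residual(self):
        pmf = pmf_from_cdf(CdfGrid(1.0, [0, 0.3]))
        rn = pmf.renormalized()
        assert rn.residual == 0.0
        assert rn.probs.sum() == pytest.approx(1.0, abs=1e-15)


class TestRescaleAndRefine:
    def test_yearly_to_monthly_value(self):
        grid = rescale_hazards(HazardGrid(1.0, [0.12]), 1 / 12)
        assert grid.hazards[0] == pytest.approx(0.01, abs=1e-15)

    def test_identity_ratio(self):
        g = HazardGrid(1.0, [0.1, 0.2])
        out = rescale_hazards(g, 1.0)
        np.testing.assert_array_equal(out.hazards, g.hazards)
        assert out.delta_t == g.delta_t

    def test_round_trip(self):
        g = HazardGrid(1.0, [0.1, 0.2, 0.05])
        back = rescale_hazards(rescale_hazards(g, 1 / 12), 12)
        np.testing.assert_allclose(back.hazards, g.hazards, atol=1e-12)
        assert back.delta_t == pytest.approx(g.delta_t, abs=1e-12)

    def test_cumulative_hazard_over_physical_span_preserved(self):
        g = HazardGrid(1.0, [0.12, 0.24])
        out = rescale_hazards(g, 1 / 12)
        assert (out.hazards * out.delta_t).sum() == pytest.approx(
            (g.hazards * g.delta_t).sum(), abs=1e-12)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rescale_hazards(HazardGrid(1.0, [0.1]), 0.0)

    def test_refine_preserves_pmf_support_mass(self):
        g = HazardGrid(1.0, [0.2, 0.4])
        fine = refine(g, 4)
        assert len(fine) == 8 and fine.delta_t == 0.25
        coarse_pmf = pmf_from_hazards(g)
        fine_pmf = pmf_from_hazards(fine)
        # mass within each original interval is unchanged
        np.testing.assert_allclose(fine_pmf.probs.reshape(2, 4).sum(axis=1),
                                   coarse_pmf.probs, atol=1e-12)


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        g = HazardGrid(0.5, [0.1, 0.2, 0.3], origin=2.0)
        path = tmp_path / "grid.csv"
        g.to_csv(path)
        back = HazardGrid.from_csv(path)
        np.testing.assert_allclose(back.hazards, g.hazards, atol=1e-12)
        assert back.delta_t == g.delta_t
        assert back.origin == g.origin

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t_start,rate\n0,0.1\n")
        with pytest.raises(ValueError, match="missing columns"):
            HazardGrid.from_csv(path)
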