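"""Unit and property tests of the measurement-model primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad as scipy_quad

from timeirt import (
    Dataset,
    ItemAccuracyParams,
    ItemTimeParams,
    LatentSpec,
    ModelSpec,
    QuadratureSpec,
    grm_category_probs,
    grm_cumulative_prob,
    implied_logtime_moments,
    logtime_density,
    marginal_loglik,
    person_loglik,
)

from conftest import grid_marginal_loglik


def valid_items():
    """Hypothesis strategy for valid GRM items (1 or 2 thresholds)."""
    return st.builds(
        lambda a, b1, gap: ItemAccuracyParams(a, (b1,) if gap is None else (b1, b1 + gap)),
        a=st.floats(0.3, 3.0),
        b1=st.floats(-3.0, 3.0),
        gap=st.one_of(st.none(), st.floats(0.1, 3.0)),
    )


class TestGrmProbabilities:
    def test_logistic_midpoint(self):
        item = ItemAccuracyParams(1.0, (0.0,))
        assert grm_cumulative_prob(0.0, item, 1) == pytest.approx(0.5)

    def test_logistic_value(self):
        # independent evaluation of 1 / (1 + exp(-2))
        item = ItemAccuracyParams(2.0, (0.0,))
        assert grm_cumulative_prob(1.0, item, 1) == pytest.approx(0.8807970779778823, abs=1e-9)

    def test_saturation(self):
        item = ItemAccuracyParams(1.5, (0.3,))
        assert grm_cumulative_prob(60.0, item, 1) == pytest.approx(1.0)
        assert grm_cumulative_prob(-60.0, item, 1) == pytest.approx(0.0)

    def test_category_index_out_of_range(self):
        item = ItemAccuracyParams(1.0, (0.0,))
        with pytest.raises(IndexError):
            grm_cumulative_prob(0.0, item, 2)
        with pytest.raises(IndexError):
            grm_cumulative_prob(0.0, item, 0)

    def test_dichotomous_midpoint(self):
        item = ItemAccuracyParams(1.0, (0.0,))
        np.testing.assert_allclose(grm_category_probs(np.array(0.0), item), [0.5, 0.5])

    def test_dichotomous_equals_2pl(self):
        # with a single threshold the GRM is the two-parameter logistic model
        item = ItemAccuracyParams(1.7, (0.4,))
        theta = np.linspace(-4, 4, 41)
        p2pl = 1.0 / (1.0 + np.exp(-1.7 * (theta - 0.4)))
        probs = grm_category_probs(theta, item)
        np.testing.assert_allclose(probs[:, 1], p2pl, rtol=0, atol=1e-15)
        np.testing.assert_allclose(probs[:, 0], 1 - p2pl, rtol=0, atol=1e-15)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ItemAccuracyParams(1.0, (0.5, 0.2))
        with pytest.raises(ValueError):
            ItemAccuracyParams(-0.5, (0.0,))

    @settings(max_examples=60, deadline=None)
    @given(item=valid_items(), theta=st.floats(-6, 6))
    def test_probs_simplex(self, item, theta):
        p = grm_category_probs(np.array(theta), item)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1) < 1e-12

    @settings(max_examples=40, deadline=None)
    @given(item=valid_items())
    def test_cumulative_monotone(self, item):
        theta = np.linspace(-6, 6, 25)
        for k in range(1, len(item.thresholds) + 1):
            vals = grm_cumulative_prob(theta, item, k)
            assert np.all(np.diff(vals) > 0)  # increasing in theta
        if len(item.thresholds) == 2:
            p1 = grm_cumulative_prob(theta, item, 1)
            p2 = grm_cumulative_prob(theta, item, 2)
            assert np.all(p1 > p2)  # decreasing in category


class TestTimeDensity:
    ITEM = ItemTimeParams(0.5, 0.3, 0.25)

    def test_median_and_mode(self):
        # lognormal: median exp(mu), mode exp(mu - sigma^2)
        mu = self.ITEM.intensity  # tau = 0
        half, _ = scipy_quad(lambda t: logtime_density(t, 0.0, 0.0, self.ITEM), 0, math.exp(mu))
        assert half == pytest.approx(0.5, abs=1e-8)
        mode = math.exp(mu - self.ITEM.residual_var)
        eps = 1e-4
        f0 = logtime_density(mode, 0.0, 0.0, self.ITEM)
        assert f0 > logtime_density(mode * (1 + eps), 0.0, 0.0, self.ITEM)
        assert f0 > logtime_density(mode * (1 - eps), 0.0, 0.0, self.ITEM)

    def test_normalization(self):
        val, _ = scipy_quad(lambda t: logtime_density(t, 0.5, -0.3, self.ITEM), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_cross_loading_shift(self):
        item = ItemTimeParams(0.5, 0.3, 0.25, cross_loading=0.2)
        # under M3 a unit increase in theta shifts the log-scale mean by phi
        t = 1.3
        d1 = logtime_density(t, 1.0, 0.0, item, "M3")
        d0 = logtime_density(t * math.exp(-0.2), 0.0, 0.0, item, "M3")
        assert d1 * t == pytest.approx(d0 * t * math.exp(-0.2), rel=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            logtime_density(0.0, 0.0, 0.0, self.ITEM)
        with pytest.raises(ValueError):
            logtime_density(-1.0, 0.0, 0.0, self.ITEM)

    def test_m3_phi_zero_equals_m2(self):
        item3 = ItemTimeParams(0.5, 0.3, 0.25, 0.0)
        for t in (0.3, 1.0, 2.7):
            assert logtime_density(t, 1.3, 0.4, item3, "M3") == pytest.approx(
                logtime_density(t, 1.3, 0.4, self.ITEM, "M2"), rel=1e-14)


class TestPersonLoglik:
    def test_all_missing_gives_zero(self, toy_m2):
        nanrow = np.full(3, np.nan)
        assert person_loglik(nanrow, nanrow, 0.3, -0.2, toy_m2) == 0.0

    def test_m1_ignores_times(self, toy_items):
        spec = ModelSpec("M1", toy_items)
        x = np.array([1.0, 2.0, 0.0])
        a = person_loglik(x, np.array([1.0, 1.0, 1.0]), 0.5, 0.0, spec)
        b = person_loglik(x, np.full(3, np.nan), 0.5, 9.9, spec)
        assert a == b

    def test_two_item_hand_computation(self):
        items = (ItemAccuracyParams(1.0, (0.0,)), ItemAccuracyParams(2.0, (-1.0,)))
        tim = (ItemTimeParams(0.5, 0.3, 0.25), ItemTimeParams(0.2, 0.4, 0.16))
        spec = ModelSpec("M2", items, tim, LatentSpec())
        theta, tau = 0.8, -0.5
        x = np.array([1.0, 0.0])
        t = np.array([1.4, 0.9])
        expected = (
            math.log(1 / (1 + math.exp(-0.8)))                       # P(X1=1)
            + math.log(1 - 1 / (1 + math.exp(-2 * (0.8 + 1.0))))     # P(X2=0)
            + math.log(math.exp(-(math.log(1.4) - (0.5 + 0.15)) ** 2 / 0.5)
                       / (1.4 * math.sqrt(2 * math.pi * 0.25)))
            + math.log(math.exp(-(math.log(0.9) - (0.2 + 0.2)) ** 2 / 0.32)
                       / (0.9 * math.sqrt(2 * math.pi * 0.16)))
        )
        assert person_loglik(x, t, theta, tau, spec) == pytest.approx(expected, rel=1e-12)


class TestMarginalLoglik:
    def test_matches_grid_oracle_m2(self, toy_data, toy_m2):
        oracle = grid_marginal_loglik(toy_data, toy_m2)
        val = marginal_loglik(toy_data, toy_m2, QuadratureSpec(21))
        assert val == pytest.approx(oracle, rel=1e-6)

    def test_matches_grid_oracle_m3(self, toy_data, toy_m3):
        oracle = grid_marginal_loglik(toy_data, toy_m3)
        val = marginal_loglik(toy_data, toy_m3, QuadratureSpec(21))
        assert val == pytest.approx(oracle, rel=1e-6)

    def test_matches_grid_oracle_m1(self, toy_data, toy_items):
        spec = ModelSpec("M1", toy_items)
        oracle = grid_marginal_loglik(toy_data, spec)
        assert marginal_loglik(toy_data, spec) == pytest.approx(oracle, rel=1e-6)

    def test_m3_with_zero_phi_equals_m2(self, toy_data, toy_items, toy_time_items):
        lat = LatentSpec(0.1, 1.2, -0.1, 0.9, 0.0)
        m2 = ModelSpec("M2", toy_items, toy_time_items, lat)
        m3 = ModelSpec("M3", toy_items, toy_time_items, lat)
        assert marginal_loglik(toy_data, m3) == pytest.approx(
            marginal_loglik(toy_data, m2), abs=1e-10)

    def test_quadrature_convergence(self, toy_data, toy_m2):
        # at a converged node count, doubling the nodes no longer moves the value
        a = marginal_loglik(toy_data, toy_m2, QuadratureSpec(45))
        b = marginal_loglik(toy_data, toy_m2, QuadratureSpec(90))
        assert abs(a - b) < 1e-8

    def test_person_relabeling_invariance(self, toy_data, toy_m2):
        perm = np.array([4, 2, 0, 3, 1])
        shuffled = Dataset(toy_data.responses[perm], toy_data.times[perm],
                           toy_data.group[perm])
        assert marginal_loglik(shuffled, toy_m2) == pytest.approx(
            marginal_loglik(toy_data, toy_m2), abs=1e-10)

    def test_item_permutation_invariance(self, toy_data, toy_m2):
        perm = [2, 0, 1]
        permuted_spec = ModelSpec(
            "M2",
            tuple(toy_m2.item_acc[i] for i in perm),
            tuple(toy_m2.item_time[i] for i in perm),
            toy_m2.latent)
        permuted_data = Dataset(toy_data.responses[:, perm], toy_data.times[:, perm],
                                toy_data.group)
        assert marginal_loglik(permuted_data, permuted_spec) == pytest.approx(
            marginal_loglik(toy_data, toy_m2), abs=1e-10)


class TestImpliedMoments:
    def test_m2_offdiagonal(self):
        items = (ItemAccuracyParams(1.0, (0.0,)), ItemAccuracyParams(1.0, (0.0,)))
        tim = (ItemTimeParams(0.0, 0.4, 0.2), ItemTimeParams(0.0, 0.5, 0.2))
        spec = ModelSpec("M2", items, tim, LatentSpec())
        mean, cov = implied_logtime_moments(spec)
        assert cov[0, 1] == pytest.approx(0.20)
        np.testing.assert_allclose(np.diag(cov), [0.4 ** 2 + 0.2, 0.5 ** 2 + 0.2])

    def test_no_common_factor(self):
        items = (ItemAccuracyParams(1.0, (0.0,)),) * 2
        tim = (ItemTimeParams(0.3, 0.0, 0.2), ItemTimeParams(0.1, 0.0, 0.3))
        _, cov = implied_logtime_moments(ModelSpec("M2", items, tim, LatentSpec()))
        np.testing.assert_allclose(cov, np.diag([0.2, 0.3]))

    def test_m3_centered_mean(self, toy_m3):
        mean, _ = implied_logtime_moments(toy_m3)
        xi = [it.intensity for it in toy_m3.item_time]
        phi = np.array([it.cross_loading for it in toy_m3.item_time])
        np.testing.assert_allclose(mean, xi + phi * toy_m3.latent.mean_theta)

    def test_monte_carlo_agreement(self, toy_m2):
        rng = np.random.default_rng(42)
        lat = toy_m2.latent
        c = lat.corr * math.sqrt(lat.var_theta * lat.var_tau)
        z = rng.multivariate_normal([lat.mean_theta, lat.mean_tau],
                                    [[lat.var_theta, c], [c, lat.var_tau]], size=200_000)
        logt = np.column_stack([
            it.intensity - it.speed_loading * z[:, 1]
            + math.sqrt(it.residual_var) * rng.standard_normal(len(z))
            for it in toy_m2.item_time])
        mean, cov = implied_logtime_moments(toy_m2)
        np.testing.assert_allclose(logt.mean(axis=0), mean, atol=0.01)
        np.testing.assert_allclose(np.cov(logt.T), cov, atol=0.01)

    def test_m1_unsupported(self, toy_items):
        with pytest.raises(ValueError):
            implied_logtime_moments(ModelSpec("M1", toy_items))


class TestDatasetValidation:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            Dataset(np.zeros((3, 2)), np.ones((3, 3)), np.array(["a"] * 3))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            Dataset(np.zeros((2, 2)), -np.ones((2, 2)), np.array(["a", "a"]))

    def test_subset_by_group(self, toy_data):
        sub = toy_data.subset("B")
        assert sub.n_persons == 3
        assert set(sub.group) == {"B"}
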