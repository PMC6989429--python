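"""Squeezing-average and polyserial starting values."""

import numpy as np
import pytest
from scipy import stats

import grmcal as g
from grmcal.initial_values import (CategoryPassRates, ScoreGroupedAbilities,
                                   inverse_normal_approx, monotonize,
                                   polyserial_initial, squeeze_initial_b,
                                   trimmed_mean)


def simulate_item_data(item, n, rng, theta_sd=1.0):
    thetas = np.clip(rng.normal(0, theta_sd, n), -3, 3)
    cum = np.cumsum(g.PackedItems.from_items([item]).category_probs(
        np.broadcast_to(thetas, (1, n)))[0], axis=1)
    scores = (rng.random(n)[:, None] > cum[:, :-1]).sum(axis=1)
    return thetas, scores


class TestSqueeze:
    def test_hand_computed_boundary(self):
        groups = ScoreGroupedAbilities([np.array([-2.0, -1.0, 0.0]),
                                        np.array([0.0, 1.0, 2.0])])
        b = squeeze_initial_b(groups, trim=0.05)  # floor(0.05*3) = 0 trimmed
        assert b == pytest.approx([0.0])

    def test_constant_groups(self):
        groups = ScoreGroupedAbilities([np.full(10, 0.7), np.full(8, 0.7)])
        assert squeeze_initial_b(groups) == pytest.approx([0.7])

    def test_trimming_removes_floor_of_each_tail(self):
        vals = np.arange(40.0)  # floor(0.05*40) = 2 from each end
        assert trimmed_mean(vals, 0.05) == pytest.approx(np.arange(2, 38).mean())

    def test_empty_group_returns_nan_for_fallback(self):
        groups = ScoreGroupedAbilities([np.array([0.0, 1.0]), np.array([]),
                                        np.array([2.0])])
        b = squeeze_initial_b(groups)
        assert np.isnan(b[0]) and np.isnan(b[1])

    def test_all_empty_errors(self):
        with pytest.raises(ValueError):
            squeeze_initial_b(ScoreGroupedAbilities([np.array([]), np.array([])]))

    def test_translation_equivariance(self, rng):
        thetas = rng.normal(0, 1, 500)
        scores = rng.integers(0, 4, 500)
        b0 = squeeze_initial_b(ScoreGroupedAbilities.from_responses(thetas, scores, 3))
        b1 = squeeze_initial_b(ScoreGroupedAbilities.from_responses(thetas + 0.8, scores, 3))
        assert b1 == pytest.approx(b0 + 0.8, abs=1e-12)

    def test_monte_carlo_recovery(self):
        """At N=700 with abilities known, each squeezed boundary lands
        within 0.35 of truth in at least 90% of seeds."""
        item = g.GRMItem("t", 1.5, (-1.0, 0.0, 1.0))
        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            th, sc = simulate_item_data(item, 700, rng)
            b = squeeze_initial_b(ScoreGroupedAbilities.from_responses(th, sc, 3))
            hits += bool(np.all(np.abs(b - np.array(item.b)) < 0.35))
        assert hits >= 0.90 * n_seeds


class TestInverseNormalApprox:
    def test_median_is_zero(self):
        assert inverse_normal_approx(0.5) == 0.0

    @pytest.mark.parametrize("p,expect,tol", [(0.8413, 0.99995, 1e-3),
                                              (0.975, 1.961, 2e-3)])
    def test_reference_points(self, p, expect, tol):
        assert inverse_normal_approx(p) == pytest.approx(expect, abs=tol)

    def test_error_bound_on_dense_grid(self):
        ps = np.linspace(0.005, 0.995, 2000)
        errs = [abs(inverse_normal_approx(p) - stats.norm.ppf(p)) for p in ps]
        assert max(errs) < 0.02

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.7])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            inverse_normal_approx(p)

    def test_antisymmetric(self):
        assert inverse_normal_approx(0.2) == pytest.approx(
            -inverse_normal_approx(0.8), abs=1e-12)


class TestPolyserial:
    def test_slope_map_closed_form(self):
        # r_p = 0.6 must map to a0 = 0.6 / sqrt(1 - 0.36) = 0.75; force the
        # conversion factor to 1 with a synthetic rates object
        rates = CategoryPassRates(np.array([0.5]), sigma=stats.norm.pdf(0.0),
                                  r=0.6, n=100)
        a0, b0 = polyserial_initial(rates)
        assert a0 == pytest.approx(0.75, abs=1e-12)
        assert b0 == pytest.approx([0.0], abs=1e-12)

    def test_symmetric_rates_give_symmetric_boundaries(self):
        thetas = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        scores = np.array([0, 0, 1, 2, 2])
        rates = CategoryPassRates.from_responses(thetas, scores, 2)
        assert rates.pass_rates[0] == pytest.approx(1 - rates.pass_rates[1])
        a0, b0 = polyserial_initial(rates)
        assert b0[0] == pytest.approx(-b0[1], abs=1e-9)
        assert a0 > 0

    def test_degenerate_rate_clamped(self):
        thetas = np.linspace(-2, 2, 50)
        scores = np.ones(50, int)
        scores[:10] = 0  # nobody reaches score 2: P*_2 = 0 gets clamped
        rates = CategoryPassRates.from_responses(thetas, scores, 2)
        a0, b0 = polyserial_initial(rates)
        assert np.all(np.isfinite(b0)) and np.all(np.diff(b0) > 0)

    def test_nonpositive_correlation_falls_back_to_neutral(self):
        thetas = np.linspace(-2, 2, 100)
        scores = (thetas < 0).astype(int)  # strongly negative correlation
        rates = CategoryPassRates.from_responses(thetas, scores, 1)
        a0, b0 = polyserial_initial(rates)
        assert a0 == 1.0

    def test_monte_carlo_recovery(self):
        """Known item (a=1.2, b=(-0.5, 0.8)) at N=2000 with known abilities:
        both parameters within 0.3 of truth in at least 90% of seeds."""
        item = g.GRMItem("t", 1.2, (-0.5, 0.8))
        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            rng = np.random.default_rng(2000 + s)
            th, sc = simulate_item_data(item, 2000, rng)
            rates = CategoryPassRates.from_responses(th, sc, 2)
            a0, b0 = polyserial_initial(rates)
            ok = abs(a0 - item.a) < 0.3 and np.all(
                np.abs(b0 - np.array(item.b)) < 0.3)
            hits += bool(ok)
        assert hits >= 0.90 * n_seeds


class TestInitialParams:
    def test_poly_ini_delegates(self, rng):
        item = g.GRMItem("t", 1.0, (-0.5, 0.5))
        th, sc = simulate_item_data(item, 400, rng)
        groups = ScoreGroupedAbilities.from_responses(th, sc, 2)
        rates = CategoryPassRates.from_responses(th, sc, 2)
        a0, b0 = g.initial_params("poly-ini", groups, rates)
        a_ref, b_ref = polyserial_initial(rates)
        assert a0 == a_ref
        assert b0 == pytest.approx(b_ref, abs=1e-15)

    def test_poly_sq_ini_mixes_sources(self, rng):
        item = g.GRMItem("t", 1.0, (-0.5, 0.5))
        th, sc = simulate_item_data(item, 400, rng)
        groups = ScoreGroupedAbilities.from_responses(th, sc, 2)
        rates = CategoryPassRates.from_responses(th, sc, 2)
        a0, b0 = g.initial_params("poly-sq-ini", groups, rates)
        assert a0 == polyserial_initial(rates)[0]
        assert b0 == pytest.approx(squeeze_initial_b(groups), abs=1e-12)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            g.initial_params("other", None, None)

    def test_outputs_always_monotone_and_positive(self, rng):
        from conftest import random_item
        for _ in range(100):
            item = random_item(rng, f=int(rng.integers(2, 6)))
            th, sc = simulate_item_data(item, 300, rng)
            for method in ("poly-ini", "poly-sq-ini"):
                a0, b0 = g.initial_params(method,
                                          ScoreGroupedAbilities.from_responses(th, sc, item.f),
                                          CategoryPassRates.from_responses(th, sc, item.f))
                assert a0 > 0
                assert np.all(np.diff(b0) > 0)


def test_monotonize_separates_ties():
    out = monotonize(np.array([0.5, 0.5, -1.0]))
    assert np.all(np.diff(out) > 0)
    assert out[0] == -1.0
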