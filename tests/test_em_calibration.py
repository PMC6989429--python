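"""E-step statistics, Newton M-step, OEM and MEM drivers."""

import numpy as np
import pytest

import grmcal as g
from grmcal.em_calibration import (CalibrationEvidence, CalibrationSettings,
                                   ExpectedCounts, expected_counts,
                                   marginal_loglik, mstep, mstep_objective,
                                   operational_likelihood, posterior_weights)
from conftest import random_item


def make_evidence(item, n, rng, n_op=10, grid=None, pool=None):
    """Simulated evidence: operational responses at true abilities plus a
    score on the new item."""
    grid = grid or g.make_grid()
    pool = pool or [random_item(rng, D=item.D) for _ in range(n_op)]
    thetas = np.clip(rng.normal(0, 1, n), -3, 3)
    ll = np.zeros((n, len(grid)))
    for op in pool:
        cum = np.cumsum(g.category_probs(op, thetas), axis=1)
        sc = (rng.random(n)[:, None] > cum[:, :-1]).sum(axis=1)
        logp = np.log(np.maximum(g.category_probs(op, grid.points), 1e-300))
        ll += logp[:, sc].T
    cum = np.cumsum(g.category_probs(item, thetas), axis=1)
    scores = (rng.random(n)[:, None] > cum[:, :-1]).sum(axis=1)
    return CalibrationEvidence(scores, ll, item.f), thetas


class TestOperationalLikelihood:
    def test_empty_product_is_constant(self, grid):
        L = operational_likelihood([], grid)
        assert np.all(L == 1.0)

    def test_one_dichotomous_item(self, grid):
        item = g.GRMItem("d", 1.2, (0.3,), D=1.0)
        L = operational_likelihood([(item, 1)], grid)
        expect = np.array([g.boundary_prob(item, x, 1) for x in grid.points])
        assert L == pytest.approx(expect / expect.max(), rel=1e-12)

    def test_matches_naive_product(self, grid, rng):
        items = [random_item(rng, f=2) for _ in range(3)]
        resp = [(it, int(rng.integers(0, 3))) for it in items]
        L = operational_likelihood(resp, grid)
        naive = np.ones(len(grid))
        for it, s in resp:
            naive *= g.category_probs(it, grid.points)[:, s]
        assert L == pytest.approx(naive / naive.max(), rel=1e-12)


class TestPosteriorWeights:
    def test_constant_likelihood_recovers_prior(self, grid):
        h = posterior_weights(np.ones(len(grid)), grid)
        assert h == pytest.approx(grid.weights)

    def test_normalization(self, grid, rng):
        for _ in range(1000):
            h = posterior_weights(rng.random(len(grid)) + 1e-9, grid)
            assert h.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(h >= 0)

    def test_point_mass_limit(self, grid):
        L = np.full(len(grid), 1e-12)
        L[30] = 1.0
        h = posterior_weights(L, grid)
        assert h[30] > 1 - 1e-6

    def test_all_zero_rejected(self, grid):
        with pytest.raises(ValueError):
            posterior_weights(np.zeros(len(grid)), grid)


class TestExpectedCounts:
    def test_single_examinee_one_hot(self, grid, rng):
        item = random_item(rng, f=3)
        ev, _ = make_evidence(item, 1, rng)
        counts = expected_counts(ev, grid)
        t0 = ev.scores[0]
        h = posterior_weights(np.exp(ev.op_loglik[0] - ev.op_loglik[0].max()),
                              grid)
        assert counts.r[t0] == pytest.approx(h, rel=1e-12)
        other = np.delete(np.arange(item.f + 1), t0)
        assert np.all(counts.r[other] == 0)

    def test_conservation_invariants(self, grid, rng):
        item = random_item(rng, f=4)
        ev, _ = make_evidence(item, 50, rng)
        for include in (False, True):
            counts = expected_counts(ev, grid, include_new=include,
                                     current_params=item)
            assert counts.r.sum(axis=0) == pytest.approx(counts.fbar, abs=1e-10)
            assert counts.fbar.sum() == pytest.approx(ev.n, abs=1e-10)

    def test_matches_elementwise_loop(self, rng):
        grid = g.make_grid(7, -3, 3)
        item = random_item(rng, f=2)
        ev, _ = make_evidence(item, 5, rng, n_op=3, grid=grid)
        counts = expected_counts(ev, grid, include_new=True,
                                 current_params=item)
        r = np.zeros((item.f + 1, 7))
        fbar = np.zeros(7)
        for i in range(5):
            L = np.exp(ev.op_loglik[i] - ev.op_loglik[i].max())
            L = L * g.category_probs(item, grid.points)[:, ev.scores[i]]
            h = L * grid.weights / np.sum(L * grid.weights)
            fbar += h
            r[ev.scores[i]] += h
        assert counts.r == pytest.approx(r, abs=1e-12)
        assert counts.fbar == pytest.approx(fbar, abs=1e-12)

    def test_include_new_requires_params(self, grid, rng):
        ev, _ = make_evidence(random_item(rng, f=1), 5, rng)
        with pytest.raises(ValueError):
            expected_counts(ev, grid, include_new=True)


class TestMStep:
    def test_self_consistent_counts_are_fixed_point(self, grid, rng):
        item = random_item(rng, f=3)
        p = g.category_probs(item, grid.points)        # (K, f+1)
        fbar = 100 * grid.weights
        counts = ExpectedCounts((p * fbar[:, None]).T, fbar, 100)
        out = mstep(counts, item, CalibrationSettings(), grid)
        assert out.a == pytest.approx(item.a, abs=1e-6)
        assert np.asarray(out.b) == pytest.approx(np.asarray(item.b), abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        grid = g.make_grid(7, -3, 3)
        item = g.GRMItem("t", 1.0, (-0.8, 0.6), D=1.0)
        ev, _ = make_evidence(item, 50, rng, n_op=8, grid=grid)
        counts = expected_counts(ev, grid)
        start = g.GRMItem("t", 1.0, (-1.0, 1.0), D=1.0)
        out = mstep(counts, start, CalibrationSettings(), grid)
        # exhaustive search on a 0.01 lattice around the Newton solution
        a_lat = np.arange(max(0.1, out.a - 0.3), out.a + 0.3, 0.01)
        b1_lat = np.arange(out.b[0] - 0.3, out.b[0] + 0.3, 0.01)
        b2_lat = np.arange(out.b[1] - 0.3, out.b[1] + 0.3, 0.01)
        best, best_q = None, -np.inf
        for a in a_lat:
            for b1 in b1_lat:
                qs = np.array([
                    mstep_objective(counts, a, np.array([b1, b2]), 1.0, grid)
                    for b2 in b2_lat if b2 > b1])
                if len(qs) and qs.max() > best_q:
                    best_q = qs.max()
                    b2s = [b2 for b2 in b2_lat if b2 > b1]
                    best = (a, b1, b2s[int(qs.argmax())])
        assert out.a == pytest.approx(best[0], abs=0.02)
        assert out.b[0] == pytest.approx(best[1], abs=0.02)
        assert out.b[1] == pytest.approx(best[2], abs=0.02)

    def test_objective_never_decreases(self, grid, rng):
        for _ in range(100):
            item = random_item(rng, f=int(rng.integers(1, 5)))
            ev, _ = make_evidence(item, 40, rng, n_op=5)
            counts = expected_counts(ev, grid)
            start = g.GRMItem("s", 1.0, tuple(np.linspace(-1, 1, item.f))
                              if item.f > 1 else (0.0,), D=item.D)
            out = mstep(counts, start, CalibrationSettings(), grid)
            q0 = mstep_objective(counts, start.a, np.array(start.b), item.D, grid)
            q1 = mstep_objective(counts, out.a, np.array(out.b), item.D, grid)
            assert q1 >= q0 - 1e-9
            assert np.all(np.diff(out.b) > 0) and out.a > 0

    def test_output_respects_bounds(self, grid, rng):
        item = random_item(rng, f=2)
        ev, _ = make_evidence(item, 35, rng)
        counts = expected_counts(ev, grid)
        s = CalibrationSettings(a_bounds=(0.5, 1.5), b_bounds=(-1.0, 1.0))
        out = mstep(counts, g.GRMItem("s", 1.0, (-0.5, 0.5), D=item.D), s, grid)
        assert 0.5 <= out.a <= 1.5
        assert -1.0 <= out.b[0] and out.b[-1] <= 1.0


class TestDrivers:
    def test_oem_equals_mem_capped_at_one_cycle(self, grid, rng):
        item = random_item(rng, f=3)
        ev, _ = make_evidence(item, 60, rng)
        init = (1.0, np.array([-1.0, 0.0, 1.0]))
        oem = g.calibrate_oem(ev, grid, init, D=item.D)
        mem1 = g.calibrate_mem(ev, grid, init, D=item.D, max_cycles=1)
        assert oem.a == mem1.a
        assert np.all(oem.b == mem1.b)
        assert oem.n_em_cycles == 1

    def test_em_monotone_marginal_loglik(self, grid, rng):
        """From the second cycle on, MEM is a proper EM on the joint
        marginal likelihood, which therefore never decreases."""
        for _ in range(20):
            item = random_item(rng, f=int(rng.integers(1, 4)))
            ev, _ = make_evidence(item, 50, rng)
            init = (1.0, np.linspace(-0.8, 0.8, item.f))
            res = g.calibrate_mem(ev, grid, (init[0], init[1]), D=item.D)
            trace = np.array(res.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-6)

    def test_order_invariance(self, grid, rng):
        """Permuting examinees changes nothing but the floating-point
        accumulation order of the expected counts."""
        item = random_item(rng, f=2)
        ev, _ = make_evidence(item, 40, rng)
        perm = np.random.default_rng(0).permutation(40)
        ev_perm = CalibrationEvidence(ev.scores[perm], ev.op_loglik[perm],
                                      ev.f)
        init = (1.0, np.array([-0.5, 0.5]))
        r1 = g.calibrate_mem(ev, grid, init, D=item.D)
        r2 = g.calibrate_mem(ev_perm, grid, init, D=item.D)
        assert r1.a == pytest.approx(r2.a, abs=1e-9)
        assert r1.b == pytest.approx(r2.b, abs=1e-9)
        assert r1.n_em_cycles == r2.n_em_cycles

    def test_min_sample_enforced(self, grid, rng):
        ev, _ = make_evidence(random_item(rng, f=1), 10, rng)
        with pytest.raises(ValueError, match="minimum"):
            g.calibrate_mem(ev, grid, (1.0, np.array([0.0])))

    def test_degenerate_score_level_flagged_not_divergent(self, grid, rng):
        item = random_item(rng, f=2)
        ev, _ = make_evidence(item, 50, rng)
        ev.scores[ev.scores == 2] = 1       # empty the top category
        res = g.calibrate_mem(ev, grid, (1.0, np.array([-0.5, 0.5])),
                              D=item.D)
        assert res.degenerate
        assert np.all(np.isfinite(res.b)) and np.all(np.diff(res.b) > 0)

    def test_oem_monte_carlo_recovery(self):
        """True item (a=1.5, b=(-1,0,1)), N=700, 20 known operational items:
        every parameter within 0.4 of truth in at least 90% of seeds."""
        grid = g.make_grid()
        item = g.GRMItem("t", 1.5, (-1.0, 0.0, 1.0))
        hits = 0
        n_seeds = 60
        for s in range(n_seeds):
            rng = np.random.default_rng(5000 + s)
            ev, th = make_evidence(item, 700, rng, n_op=20)
            groups = g.ScoreGroupedAbilities.from_responses(th, ev.scores, 3)
            rates = g.CategoryPassRates.from_responses(th, ev.scores, 3)
            init = g.initial_params("poly-sq-ini", groups, rates)
            res = g.calibrate_oem(ev, grid, init, D=item.D)
            ok = abs(res.a - item.a) < 0.4 and np.all(
                np.abs(res.b - np.array(item.b)) < 0.4)
            hits += bool(ok)
        assert hits >= 0.90 * n_seeds

    def test_mem_not_worse_than_oem_on_boundaries(self):
        """Paired comparison: MEM's boundary RMSE does not exceed OEM's on
        the same simulated samples (random design conditions)."""
        grid = g.make_grid()
        item = g.GRMItem("t", 1.5, (-1.0, 0.0, 1.0))
        err_oem, err_mem = [], []
        for s in range(40):
            rng = np.random.default_rng(7000 + s)
            ev, th = make_evidence(item, 700, rng, n_op=20)
            groups = g.ScoreGroupedAbilities.from_responses(th, ev.scores, 3)
            rates = g.CategoryPassRates.from_responses(th, ev.scores, 3)
            init = g.initial_params("poly-sq-ini", groups, rates)
            ro = g.calibrate_oem(ev, grid, init, D=item.D)
            rm = g.calibrate_mem(ev, grid, init, D=item.D)
            err_oem.append(ro.b - np.array(item.b))
            err_mem.append(rm.b - np.array(item.b))
        rmse_oem = np.sqrt(np.mean(np.square(err_oem)))
        rmse_mem = np.sqrt(np.mean(np.square(err_mem)))
        assert rmse_mem <= rmse_oem + 1e-6


def test_marginal_loglik_matches_direct_sum(grid, rng):
    item = random_item(rng, f=2)
    ev, _ = make_evidence(item, 8, rng, n_op=3)
    ll = marginal_loglik(ev, item, grid)
    direct = 0.0
    for i in range(8):
        L = np.exp(ev.op_loglik[i]) * \
            g.category_probs(item, grid.points)[:, ev.scores[i]]
        direct += np.log(np.sum(L * grid.weights))
    assert ll == pytest.approx(direct, rel=1e-10)
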