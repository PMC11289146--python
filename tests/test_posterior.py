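import itertools

import numpy as np
import pytest

from adaptsat import (
    SATParams,
    TrialRecord,
    build_grid,
    clamp_probability,
    estimate,
    evaluate_satf,
    init_prior,
    marginal_distribution,
    pc_hwci,
    posterior_mean_params,
    predictive_pc_curve,
    resampled_pc_curve,
    truncate_lambda,
    update_trial,
)
from adaptsat.posterior import PosteriorGrid


def degenerate(grid, idx):
    mass = np.zeros(grid.n_cells)
    mass[idx] = 1.0
    return PosteriorGrid(grid, mass)


def random_trials(rng, n, conditions=("c",)):
    trials = []
    for _ in range(n):
        soa = float(rng.uniform(0, 1.2))
        trials.append(TrialRecord(
            str(rng.choice(conditions)), soa,
            soa + float(rng.uniform(0.0001, 0.2)), int(rng.integers(2)),
        ))
    return trials


class TestPriorAndUpdate:
    def test_uniform_prior(self, small_grid):
        post = init_prior(small_grid)
        assert np.allclose(post.mass, 1.0 / small_grid.n_cells)
        assert post.mass.sum() == pytest.approx(1.0, abs=1e-12)
        lam_marg = marginal_distribution(post, "lam")
        assert np.allclose(lam_marg, 1.0 / small_grid.lam_values.size)

    def test_constant_likelihood_below_intercept(self, small_grid):
        # rt below every grid delta: psi = 0.5 everywhere, posterior unchanged
        post = init_prior(small_grid)
        updated = update_trial(post, TrialRecord("c", 0.0, 0.01, 1))
        assert np.allclose(updated.mass, post.mass, atol=1e-15)
        assert updated.trial_count == 1

    def test_two_cell_hand_bayes(self, toy2_grid):
        # at rt = 1.2 the two cells give psi ~ (0.6, 0.9); with a flat prior
        # a correct response yields mass (0.3, 0.45) / 0.75 = (0.4, 0.6)
        post = update_trial(init_prior(toy2_grid), TrialRecord("c", 1.0, 1.2, 1))
        assert np.allclose(post.mass, [0.4, 0.6], atol=1e-9)
        wrong = update_trial(init_prior(toy2_grid), TrialRecord("c", 1.0, 1.2, 0))
        assert np.allclose(wrong.mass, [0.4 / 0.5, 0.1 / 0.5], atol=1e-8)

    def test_normalization_preserved(self, small_grid):
        rng = np.random.default_rng(3)
        post = init_prior(small_grid)
        for trial in random_trials(rng, 25):
            post = update_trial(post, trial)
            assert abs(post.mass.sum() - 1.0) < 1e-10
            assert np.all(post.mass >= 0)

    def test_order_invariance(self, small_grid):
        rng = np.random.default_rng(7)
        trials = random_trials(rng, 10)
        reference = init_prior(small_grid)
        for t in trials:
            reference = update_trial(reference, t)
        for perm_seed in range(4):
            perm = np.random.default_rng(perm_seed).permutation(len(trials))
            post = init_prior(small_grid)
            for i in perm:
                post = update_trial(post, trials[i])
            assert np.allclose(post.mass, reference.mass, rtol=1e-9, atol=1e-15)

    def test_matches_bruteforce_bayes_oracle(self):
        # independent single-pass Bayes on an enumerable 2x2x2 grid
        grid = build_grid((0.4, 0.5), 2, (5.0, 20.0), 2, (0.1, 0.3), 2)
        rng = np.random.default_rng(11)
        trials = random_trials(rng, 5)
        post = init_prior(grid)
        for t in trials:
            post = update_trial(post, t)

        cells = list(itertools.product(grid.lam_values, grid.gamma_values,
                                       grid.delta_values))
        weights = []
        for lam, gamma, delta in cells:
            w = 1.0 / len(cells)
            for t in trials:
                psi = clamp_probability(evaluate_satf(SATParams(lam, gamma, delta), t.rt))
                w *= psi if t.correct else 1.0 - psi
            weights.append(w)
        expected = np.asarray(weights) / np.sum(weights)
        assert np.allclose(post.mass, expected, atol=1e-12)


class TestEstimates:
    def test_degenerate_mean_is_cell_params(self, small_grid):
        idx = 23
        p = posterior_mean_params(degenerate(small_grid, idx))
        assert p.as_tuple() == small_grid.params_at(idx).as_tuple()

    def test_uniform_means_are_midpoints(self):
        post = init_prior(build_grid(lam_range=(0.4, 0.55)))
        p = posterior_mean_params(post)
        assert p.lam == pytest.approx(0.475)
        assert p.gamma == pytest.approx(15.5)
        assert p.delta == pytest.approx(0.26)

    def test_two_cell_mean_is_average(self, small_grid):
        mass = np.zeros(small_grid.n_cells)
        mass[[4, 40]] = 0.5
        p = posterior_mean_params(PosteriorGrid(small_grid, mass))
        a, b = small_grid.params_at(4), small_grid.params_at(40)
        assert p.lam == pytest.approx((a.lam + b.lam) / 2)
        assert p.gamma == pytest.approx((a.gamma + b.gamma) / 2)
        assert p.delta == pytest.approx((a.delta + b.delta) / 2)

    @pytest.mark.parametrize("lam, expected", [(0.52, 0.50), (0.45, 0.45), (0.50, 0.50)])
    def test_truncate_lambda(self, lam, expected):
        out = truncate_lambda(SATParams(lam, 25.0, 0.2))
        assert out.lam == expected
        assert (out.gamma, out.delta) == (25.0, 0.2)

    def test_estimate_contract(self, small_grid):
        post = init_prior(small_grid)
        res = estimate(post, np.linspace(0, 1.2, 9))
        assert res.reported_params.lam <= 0.5
        assert np.all((res.mean_curve >= 0.5 - 1e-12) & (res.mean_curve <= 1.0))
        assert np.all(res.hwci_per_point >= 0)


class TestPredictiveCurve:
    def test_degenerate_curve_is_cell_satf(self, small_grid):
        idx = 10
        rts = np.linspace(0, 1.2, 7)
        curve = predictive_pc_curve(degenerate(small_grid, idx), rts)
        assert np.allclose(curve, evaluate_satf(small_grid.params_at(idx), rts))

    def test_mixture_is_pointwise_average(self, small_grid):
        rts = np.linspace(0, 1.2, 7)
        mass = np.zeros(small_grid.n_cells)
        mass[[3, 33]] = 0.5
        mix = predictive_pc_curve(PosteriorGrid(small_grid, mass), rts)
        c1 = predictive_pc_curve(degenerate(small_grid, 3), rts)
        c2 = predictive_pc_curve(degenerate(small_grid, 33), rts)
        assert np.allclose(mix, (c1 + c2) / 2)

    def test_uniform_at_chance_below_min_delta(self, small_grid):
        curve = predictive_pc_curve(init_prior(small_grid), [0.01])
        assert curve[0] == pytest.approx(0.5, abs=1e-9)

    def test_resampled_agrees_with_exact(self, small_grid):
        rng = np.random.default_rng(5)
        post = init_prior(small_grid)
        for t in random_trials(rng, 20):
            post = update_trial(post, t)
        rts = np.linspace(0, 1.2, 9)
        exact = predictive_pc_curve(post, rts)
        sampled = resampled_pc_curve(post, rts, n_samples=4000,
                                     rng=np.random.default_rng(0))
        assert np.allclose(sampled, exact, atol=0.01)


class TestHWCI:
    def test_degenerate_posterior_zero_width(self, small_grid):
        hw = pc_hwci(degenerate(small_grid, 12), np.linspace(0, 1.2, 9))
        assert np.allclose(hw, 0.0)

    def test_two_point_distribution(self, toy2_grid):
        # equal mass on accuracies (0.6, 0.9) at rt = 1.2: the shortest
        # 68.2% interval must span both values -> half-width 0.15
        hw = pc_hwci(init_prior(toy2_grid), [1.2])
        assert hw[0] == pytest.approx(0.15, abs=1e-9)

    def test_nonnegative_for_random_posterior(self, small_grid):
        rng = np.random.default_rng(9)
        post = init_prior(small_grid)
        for t in random_trials(rng, 15):
            post = update_trial(post, t)
        hw = pc_hwci(post, np.linspace(0, 1.2, 49))
        assert np.all(hw >= 0)


class TestMarginals:
    def test_degenerate_marginal_is_indicator(self, small_grid):
        idx = 31
        i, j, k = small_grid.unravel(idx)
        post = degenerate(small_grid, idx)
        assert marginal_distribution(post, "gamma")[j] == pytest.approx(1.0)

    def test_marginals_sum_to_one(self, small_grid):
        rng = np.random.default_rng(13)
        post = init_prior(small_grid)
        for t in random_trials(rng, 12):
            post = update_trial(post, t)
        for axis in ("lam", "gamma", "delta"):
            assert marginal_distribution(post, axis).sum() == pytest.approx(1.0)

    def test_unknown_axis_rejected(self, small_grid):
        with pytest.raises(ValueError):
            marginal_distribution(init_prior(small_grid), "rate")
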