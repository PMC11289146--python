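import itertools
import math

import numpy as np
import pytest

from adaptsat import (
    SATParams,
    SOADesign,
    TrialRecord,
    block_outcome_likelihood,
    build_grid,
    clamp_probability,
    evaluate_satf,
    expected_conditional_entropy,
    gain_profile,
    information_gain,
    init_prior,
    marginal_outcome_entropy,
    select_next_soa,
    update_trial,
)
from adaptsat.posterior import PosteriorGrid
from adaptsat.selection import resolve_strategy


def degenerate(grid, idx):
    mass = np.zeros(grid.n_cells)
    mass[idx] = 1.0
    return PosteriorGrid(grid, mass)


def updated_posterior(grid, seed, n=8):
    rng = np.random.default_rng(seed)
    post = init_prior(grid)
    for _ in range(n):
        soa = float(rng.uniform(0, 1.0))
        post = update_trial(post, TrialRecord(
            "c", soa, soa + float(rng.uniform(0.001, 0.2)), int(rng.integers(2))))
    return post


def outcome_pmf(params, x_hat, n):
    """Independent binomial pmf via explicit products (oracle)."""
    p = clamp_probability(evaluate_satf(params, x_hat))
    return np.array([math.comb(n, r) * p ** r * (1 - p) ** (n - r)
                     for r in range(n + 1)])


def entropy(pmf):
    pmf = np.asarray(pmf)
    nz = pmf[pmf > 0]
    return float(-(nz * np.log(nz)).sum())


class TestBlockOutcome:
    def test_bernoulli_case(self):
        p = evaluate_satf(SATParams(0.45, 25.0, 0.2), 0.4)
        pmf = block_outcome_likelihood(SATParams(0.45, 25.0, 0.2), 0.4, 1)
        assert np.allclose(pmf, [1 - p, p])

    def test_fair_binomial_below_intercept(self):
        pmf = block_outcome_likelihood(SATParams(0.45, 25.0, 0.2), 0.1, 2)
        assert np.allclose(pmf, [0.25, 0.5, 0.25])

    def test_pmf_normalized(self):
        pmf = block_outcome_likelihood(SATParams(0.3, 10.0, 0.1), 0.7, 16)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pmf >= 0)


class TestEntropies:
    def test_fair_coin_below_every_delta(self, small_grid):
        post = init_prior(small_grid)
        assert expected_conditional_entropy(post, 0.01, 1) == pytest.approx(math.log(2))
        assert marginal_outcome_entropy(post, 0.01, 1) == pytest.approx(math.log(2))

    def test_degenerate_posterior_gain_zero(self, small_grid):
        post = degenerate(small_grid, 17)
        x_hat = 0.5
        cond = expected_conditional_entropy(post, x_hat, 4)
        marg = marginal_outcome_entropy(post, x_hat, 4)
        assert marg == pytest.approx(cond, abs=1e-12)
        assert marg == pytest.approx(entropy(
            outcome_pmf(small_grid.params_at(17), x_hat, 4)))

    def test_matches_enumeration_oracle(self, toy2_grid):
        post = PosteriorGrid(toy2_grid, np.array([0.3, 0.7]))
        n, x_hat = 2, 0.9
        pmfs = [outcome_pmf(toy2_grid.params_at(i), x_hat, n) for i in range(2)]
        cond_oracle = 0.3 * entropy(pmfs[0]) + 0.7 * entropy(pmfs[1])
        marg_oracle = entropy(0.3 * pmfs[0] + 0.7 * pmfs[1])
        assert expected_conditional_entropy(post, x_hat, n) == pytest.approx(
            cond_oracle, abs=1e-12)
        assert marginal_outcome_entropy(post, x_hat, n) == pytest.approx(
            marg_oracle, abs=1e-12)

    def test_marginal_dominates_conditional(self, small_grid):
        post = updated_posterior(small_grid, seed=2)
        for x_hat in (0.1, 0.3, 0.8):
            assert (marginal_outcome_entropy(post, x_hat, 8)
                    >= expected_conditional_entropy(post, x_hat, 8) - 1e-12)


class TestInformationGain:
    def test_additivity_matches_joint_enumeration(self, toy2_grid):
        """The sum rule equals the mutual information of the joint outcome
        pair computed by full enumeration over both conditions."""
        post1 = PosteriorGrid(toy2_grid, np.array([0.3, 0.7]))
        post2 = PosteriorGrid(toy2_grid, np.array([0.6, 0.4]))
        n, soa = 2, 0.8
        x_hat = soa + 0.1
        pmfs1 = [outcome_pmf(toy2_grid.params_at(i), x_hat, n) for i in range(2)]
        pmfs2 = [outcome_pmf(toy2_grid.params_at(i), x_hat, n) for i in range(2)]

        joint_marg = np.zeros((n + 1, n + 1))
        cond_H = 0.0
        for (i, w1), (j, w2) in itertools.product(
                enumerate(post1.mass), enumerate(post2.mass)):
            joint = np.outer(pmfs1[i], pmfs2[j])
            joint_marg += w1 * w2 * joint
            cond_H += w1 * w2 * entropy(joint.ravel())
        mi_joint = entropy(joint_marg.ravel()) - cond_H

        gain = information_gain([post1, post2], soa, n_per_condition=n)
        assert gain == pytest.approx(mi_joint, abs=1e-10)
        assert gain >= 0

    def test_degenerate_posteriors_zero_gain(self, small_grid):
        posts = [degenerate(small_grid, 3), degenerate(small_grid, 40)]
        assert information_gain(posts, 0.5, 4) == pytest.approx(0.0, abs=1e-12)

    def test_single_condition_reduces_to_one_term(self, small_grid):
        post = updated_posterior(small_grid, seed=4)
        soa = 0.4
        x_hat = soa + 0.1
        single = (marginal_outcome_entropy(post, x_hat, 8)
                  - expected_conditional_entropy(post, x_hat, 8))
        assert information_gain([post], soa, 8) == pytest.approx(single, abs=1e-12)


class TestSelection:
    def test_profile_consistent_with_ops_and_argmax(self, small_grid):
        design = SOADesign(np.linspace(0.0, 1.2, 13))
        posts = [updated_posterior(small_grid, seed=5),
                 updated_posterior(small_grid, seed=6)]
        profile = gain_profile(posts, design, "sum", n_per_condition=4)
        # exhaustive per-SOA oracle through the scalar operations
        oracle = np.array([information_gain(posts, s, 4) for s in design.soa_values])
        assert np.allclose(profile, oracle, atol=1e-10)
        assert np.all(profile >= -1e-12)
        plan = select_next_soa(posts, design, "sum", 4)
        assert plan.soa == design.soa_values[np.argmax(profile)]
        assert plan.expected_rt == pytest.approx(plan.soa + 0.1)

    def test_sum_profile_is_elementwise_sum(self, small_grid):
        design = SOADesign(np.linspace(0.0, 1.2, 13))
        posts = [updated_posterior(small_grid, seed=8),
                 updated_posterior(small_grid, seed=9)]
        total = gain_profile(posts, design, "sum", 4)
        parts = [gain_profile(posts, design, k, 4) for k in (0, 1)]
        assert np.allclose(total, parts[0] + parts[1], atol=1e-12)

    def test_identical_posteriors_match_single_condition_choice(self, small_grid):
        design = SOADesign(np.linspace(0.0, 1.2, 13))
        post = updated_posterior(small_grid, seed=10)
        same = [post, post.copy()]
        assert (select_next_soa(same, design, "sum", 4).soa
                == select_next_soa(same, design, 0, 4).soa)

    def test_degenerate_tie_breaks_to_smallest_soa(self, small_grid):
        design = SOADesign.default()
        posts = [degenerate(small_grid, 1), degenerate(small_grid, 50)]
        assert select_next_soa(posts, design, "sum", 4).soa == 0.0

    def test_argmax_invariant_to_log_base(self, small_grid):
        design = SOADesign(np.linspace(0.0, 1.2, 13))
        post = updated_posterior(small_grid, seed=12)
        profile_nats = gain_profile([post], design, 0, 4)
        profile_bits = profile_nats / math.log(2)  # entropies rescale linearly
        assert np.argmax(profile_nats) == np.argmax(profile_bits)

    def test_strategy_resolution(self):
        assert resolve_strategy("sum", 2) is None
        assert resolve_strategy("1", 2) == 0
        assert resolve_strategy("2", 2) == 1
        assert resolve_strategy(1, 2) == 1
        with pytest.raises(ValueError):
            resolve_strategy("3", 2)
        with pytest.raises(ValueError):
            resolve_strategy("best", 2)
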