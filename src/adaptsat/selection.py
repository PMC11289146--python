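"""Information-based choice of the next block's stimulus-onset asynchrony.

A block of ``n`` trials per condition at SOA ``T`` will produce, for each
condition, a count of correct responses modelled as Binomial(n, psi(theta,
x_hat)) with ``x_hat = T + window / 2`` the expected response time.  The
expected information gain of testing ``T`` is the mutual information between
that outcome count and the condition's parameters under the current
posterior; for several concurrently estimated conditions the counts are
independent given the parameters, so the joint gain decomposes into the sum
of per-condition gains (the "sum rule").  Selection picks the SOA with the
largest gain — over a single condition's gain (the single-condition
strategies) or over the sum.

Entropies are in nats; the argmax is invariant to the logarithm base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from ._tables import entropy_nats, get_design_tables
from .model import (
    EPS,
    InvalidConfigError,
    SATParams,
    SOADesign,
    clamp_probability,
    evaluate_satf,
)
from .posterior import PosteriorGrid

#: Default number of trials per condition in one block.
DEFAULT_BLOCK_SIZE = 16

Strategy = Union[str, int]


@dataclass(frozen=True)
class BlockPlan:
    """The chosen SOA for the next block and its planning quantities."""

    soa: float
    expected_rt: float
    n_per_condition: int

    def __post_init__(self) -> None:
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")


def resolve_strategy(strategy: Strategy, n_conditions: int) -> int | None:
    """Normalize a strategy spec to a 0-based condition index or None (sum).

    Accepts ``"sum"``, a 0-based integer index, or the 1-based string form
    used on the command line (``"1"``, ``"2"``, ...).
    """
    if isinstance(strategy, str):
        s = strategy.strip().lower()
        if s == "sum":
            return None
        if s.isdigit():
            idx = int(s) - 1  # CLI strategies are 1-based
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    elif isinstance(strategy, (int, np.integer)):
        idx = int(strategy)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not 0 <= idx < n_conditions:
        raise ValueError(
            f"strategy condition index {idx} out of range for {n_conditions} conditions"
        )
    return idx


def block_outcome_likelihood(params: SATParams, expected_rt: float, n: int,
                             eps: float = EPS) -> np.ndarray:
    """Binomial pmf over 0..n correct responses in a block at ``expected_rt``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p = clamp_probability(evaluate_satf(params, expected_rt), eps)
    from scipy.stats import binom

    return binom.pmf(np.arange(n + 1), n, p)


def _outcome_pmf_cells(post: PosteriorGrid, expected_rt: float, n: int,
                       eps: float) -> np.ndarray:
    """Outcome pmf per grid cell, shape (n + 1, n_cells)."""
    from scipy.stats import binom

    from .model import satf_grid_table

    p = satf_grid_table(post.grid, [expected_rt], eps)[0]
    return binom.pmf(np.arange(n + 1)[:, np.newaxis], n, p[np.newaxis, :])


def expected_conditional_entropy(post: PosteriorGrid, expected_rt: float,
                                 n: int, eps: float = EPS) -> float:
    """Posterior-expected entropy of the block outcome given the parameters."""
    pmf = _outcome_pmf_cells(post, expected_rt, n, eps)
    return float(entropy_nats(pmf, axis=0) @ post.mass)


def marginal_outcome_entropy(post: PosteriorGrid, expected_rt: float,
                             n: int, eps: float = EPS) -> float:
    """Entropy of the posterior-predictive block outcome distribution."""
    pmf = _outcome_pmf_cells(post, expected_rt, n, eps)
    return float(entropy_nats(pmf @ post.mass, axis=0))


def information_gain(posts: Sequence[PosteriorGrid], soa: float,
                     n_per_condition: int = DEFAULT_BLOCK_SIZE,
                     response_window: float = 0.2, eps: float = EPS) -> float:
    """Summed per-condition mutual information of a block at ``soa``, nats.

    Mutual information is nonnegative; tiny negative rounding residue is
    floored at zero.
    """
    if len(posts) == 0:
        raise ValueError("at least one condition posterior is required")
    x_hat = float(soa) + response_window / 2.0
    gain = sum(
        marginal_outcome_entropy(p, x_hat, n_per_condition, eps)
        - expected_conditional_entropy(p, x_hat, n_per_condition, eps)
        for p in posts
    )
    return max(gain, 0.0)


def gain_profile(posts: Sequence[PosteriorGrid], soa_design: SOADesign,
                 strategy: Strategy = "sum",
                 n_per_condition: int = DEFAULT_BLOCK_SIZE,
                 eps: float = EPS) -> np.ndarray:
    """Expected information gain at every candidate SOA.

    For strategy ``"sum"`` this is the elementwise sum of the single-condition
    profiles; for a condition-index strategy it is that condition's profile
    alone.
    """
    if len(posts) == 0:
        raise ValueError("at least one condition posterior is required")
    idx = resolve_strategy(strategy, len(posts))
    selected = posts if idx is None else [posts[idx]]
    profile = np.zeros(soa_design.n_soas)
    for post in selected:
        tables = get_design_tables(post.grid, soa_design, n_per_condition, eps)
        profile += tables.gain_profile(post.mass)
    return profile


def select_next_soa(posts: Sequence[PosteriorGrid], soa_design: SOADesign,
                    strategy: Strategy = "sum",
                    n_per_condition: int = DEFAULT_BLOCK_SIZE,
                    eps: float = EPS) -> BlockPlan:
    """SOA with the maximum expected information gain for the next block.

    Ties are broken toward the smallest SOA: any candidate whose gain is
    within 1e-12 nats of the maximum counts as tied (absorbing floating-point
    noise, e.g. the all-zero profile of a degenerate posterior), and the
    earliest such SOA wins, which makes selection deterministic.
    """
    if soa_design.n_soas == 0:
        raise InvalidConfigError("SOA design has no candidate values")
    profile = gain_profile(posts, soa_design, strategy, n_per_condition, eps)
    i = int(np.argmax(profile >= profile.max() - 1e-12))
    soa = float(soa_design.soa_values[i])
    return BlockPlan(soa, soa_design.expected_rt(soa), n_per_condition)
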