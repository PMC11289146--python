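"""Grid posterior over SAT-function parameters for one task condition.

The posterior is a probability mass function over the cells of a
:class:`~adaptsat.model.ParameterGrid`.  Each observed trial multiplies the
mass by the Bernoulli likelihood of the binarized response at the recorded
response time and renormalizes; point estimates are marginal posterior
means, the predictive accuracy curve is the exact posterior expectation of
the (clamped) SAT function, and precision is summarized by mass-weighted
credible half-widths of the predicted accuracy at each evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    EPS,
    LAM_LIMIT,
    ParameterGrid,
    SATParams,
    _satf,
    satf_grid_table,
)

#: Tolerance on posterior normalization.
NORM_TOL = 1e-10

_AXES = ("lam", "gamma", "delta")


class NumericalError(ArithmeticError):
    """Raised when a Bayesian update would leave zero total mass."""


@dataclass(frozen=True)
class TrialRecord:
    """One observed response-signal trial.

    ``correct`` is binary (1 correct / 0 incorrect); ``soa`` and ``rt`` are
    in seconds.  For response-signal data the response time should lie in
    ``(soa, soa + window]`` but this is not enforced here, so recorded logs
    with stray rows can still be replayed.
    """

    condition: str
    soa: float
    rt: float
    correct: int

    def __post_init__(self) -> None:
        if self.correct not in (0, 1):
            raise ValueError(f"correct must be 0 or 1, got {self.correct!r}")
        if not (np.isfinite(self.soa) and np.isfinite(self.rt)):
            raise ValueError("soa and rt must be finite")
        if self.rt < 0 or self.soa < 0:
            raise ValueError("soa and rt must be >= 0")


@dataclass
class PosteriorGrid:
    """Normalized probability mass over a parameter grid."""

    grid: ParameterGrid
    mass: np.ndarray
    trial_count: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        if m.shape != (self.grid.n_cells,):
            raise ValueError(
                f"mass must have shape ({self.grid.n_cells},), got {m.shape}"
            )
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("mass must be finite and nonnegative")
        total = m.sum()
        if abs(total - 1.0) > NORM_TOL:
            raise ValueError(f"mass must sum to 1 within {NORM_TOL}, got {total}")
        self.mass = m

    def copy(self) -> "PosteriorGrid":
        return PosteriorGrid(self.grid, self.mass.copy(), self.trial_count)


def init_prior(grid: ParameterGrid) -> PosteriorGrid:
    """Uniform prior: every cell carries mass ``1 / n_cells``."""
    n = grid.n_cells
    return PosteriorGrid(grid, np.full(n, 1.0 / n), trial_count=0)


def trial_likelihood(grid: ParameterGrid, rt: float, correct: int,
                     eps: float = EPS) -> np.ndarray:
    """Per-cell Bernoulli likelihood of one response at response time ``rt``.

    ``clamp(psi(theta, rt))`` for a correct response and its complement for
    an incorrect one; the complement case follows from the probability
    axioms.
    """
    psi = np.clip(
        _satf(grid.lam_flat, grid.gamma_flat, grid.delta_flat, rt), eps, 1.0 - eps
    )
    return psi if correct else 1.0 - psi


def update_trial(post: PosteriorGrid, trial: TrialRecord,
                 eps: float = EPS) -> PosteriorGrid:
    """Bayes update of the posterior with one trial; returns a new posterior.

    Raises :class:`NumericalError` if the updated mass would not normalize
    (cannot happen while likelihoods are clamped away from 0, but guarded
    anyway).
    """
    like = trial_likelihood(post.grid, trial.rt, trial.correct, eps)
    m = post.mass * like
    total = m.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise NumericalError("posterior update produced non-normalizable mass")
    return PosteriorGrid(post.grid, m / total, post.trial_count + 1)


def posterior_mean_params(post: PosteriorGrid) -> SATParams:
    """Marginal posterior mean of each parameter."""
    g = post.grid
    return SATParams(
        float(post.mass @ g.lam_flat),
        float(post.mass @ g.gamma_flat),
        float(post.mass @ g.delta_flat),
    )


def truncate_lambda(params: SATParams, limit: float = LAM_LIMIT) -> SATParams:
    """Truncate a reported asymptote estimate at the theoretical limit.

    Applied only to reported estimates when the lam axis is padded beyond
    the limit; the posterior itself is never modified.
    """
    return SATParams(min(params.lam, limit), params.gamma, params.delta)


def predictive_pc_curve(post: PosteriorGrid, eval_rts, eps: float = EPS) -> np.ndarray:
    """Posterior-mean predicted accuracy at each evaluation response time.

    The exact grid expectation ``sum_theta mass(theta) * clamp(psi(theta, rt))``
    — the infinite-resample limit of averaging SAT functions drawn from the
    posterior (see :func:`resampled_pc_curve` for the sampling analogue).
    """
    table = satf_grid_table(post.grid, eval_rts, eps)
    return table @ post.mass


def resampled_pc_curve(post: PosteriorGrid, eval_rts, n_samples: int = 1000,
                       rng: np.random.Generator | None = None,
                       eps: float = EPS) -> np.ndarray:
    """Monte-Carlo predicted accuracy from ``n_samples`` posterior draws.

    Provided as a fidelity check on :func:`predictive_pc_curve`; agrees with
    it up to sampling error of order ``1 / sqrt(n_samples)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.choice(post.grid.n_cells, size=n_samples, p=post.mass)
    table = satf_grid_table(post.grid, eval_rts, eps)
    return table[:, idx].mean(axis=1)


def pc_hwci(post: PosteriorGrid, eval_rts, interval: float = 0.682,
            eps: float = EPS) -> np.ndarray:
    """Credible half-width of predicted accuracy at each evaluation time.

    At each ``rt`` the grid cells induce a mass-weighted discrete
    distribution of accuracy values; the half-width is half the length of
    the shortest (highest-density) interval covering at least ``interval``
    of that mass.  See :meth:`adaptsat._tables.EvalTables.hwci` for the
    deterministic minimization convention.
    """
    from ._tables import get_eval_tables

    return get_eval_tables(post.grid, eval_rts, eps).hwci(post.mass, interval)


def marginal_distribution(post: PosteriorGrid, axis: str) -> np.ndarray:
    """Marginal posterior mass over one parameter axis (sums to 1)."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
    cube = post.mass.reshape(post.grid.shape)
    keep = _AXES.index(axis)
    return cube.sum(axis=tuple(i for i in range(3) if i != keep))


@dataclass
class EstimationResult:
    """Point estimates and predictive summaries extracted from a posterior.

    ``raw_means`` are the marginal posterior means; ``reported_params`` have
    the asymptote truncated at the theoretical limit.  ``mean_curve`` and
    ``hwci_per_point`` are evaluated at ``eval_rts``.
    """

    raw_means: SATParams
    reported_params: SATParams
    eval_rts: np.ndarray = field(repr=False)
    mean_curve: np.ndarray = field(repr=False)
    hwci_per_point: np.ndarray = field(repr=False)

    @property
    def mean_hwci(self) -> float:
        """HWCI averaged over evaluation points (the headline precision)."""
        return float(np.mean(self.hwci_per_point))


def estimate(post: PosteriorGrid, eval_rts, lam_limit: float = LAM_LIMIT,
             interval: float = 0.682, eps: float = EPS) -> EstimationResult:
    """Full estimation summary for one condition's posterior."""
    eval_rts = np.atleast_1d(np.asarray(eval_rts, dtype=float))
    raw = posterior_mean_params(post)
    return EstimationResult(
        raw_means=raw,
        reported_params=truncate_lambda(raw, lam_limit),
        eval_rts=eval_rts,
        mean_curve=predictive_pc_curve(post, eval_rts, eps),
        hwci_per_point=pc_hwci(post, eval_rts, interval, eps),
    )
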