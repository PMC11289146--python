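"""Virtual response-signal participants and full session simulation.

A virtual participant owns one true SAT parameter triple per task condition
and an ex-Gaussian response-time law.  On a trial at SOA ``T`` the response
time is drawn from the ex-Gaussian density truncated and renormalized to the
response window ``(T, T + window]`` — the participant can only answer while
the response signal is on — and the response is correct with probability
equal to the true SAT function at the sampled response time.

Adaptive sessions interleave all conditions within fixed-SOA blocks, update
each condition's grid posterior after every trial, and pick the next block's
SOA by expected information gain.  Method-of-constant-stimuli (MCS) sessions
visit a fixed SOA set in seeded random block order with no adaptivity.

Randomness is structured for reproducibility: a session seed is expanded
into one independent substream per condition (consumed as a (trial, [rt,
response]) uniform table) plus one for block/interleaving order, so the same
seed always reproduces the identical session and different conditions never
share RNG state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import exponnorm

from .model import (
    EPS,
    LAM_LIMIT,
    ParameterGrid,
    SATParams,
    SOADesign,
    build_grid,
    clamp_probability,
    evaluate_satf,
)
from .posterior import (
    EstimationResult,
    PosteriorGrid,
    TrialRecord,
    estimate,
    init_prior,
    posterior_mean_params,
    update_trial,
)
from .selection import DEFAULT_BLOCK_SIZE, Strategy, select_next_soa
from ._tables import get_eval_tables

logger = logging.getLogger(__name__)

#: MCS stimulus set used by the flanker validation experiment (seconds).
DEFAULT_MCS_SOAS = (0.06, 0.09, 0.12, 0.24, 0.36, 0.48, 0.60, 1.20)

#: Below this much ex-Gaussian mass in a window, fall back to a uniform draw.
_MIN_WINDOW_MASS = 1e-14

TRIAL_LOG_COLUMNS = ["block", "trial", "condition", "soa", "rt", "correct"]


@dataclass(frozen=True)
class ExGaussianSpec:
    """Ex-Gaussian response-time law: Normal(mu, sigma) + Exponential(tau).

    Defaults (mu=0.3 s, sigma=0.06 s, tau=0.08 s) describe a typical fast
    perceptual-decision RT distribution with mean ``mu + tau`` = 0.38 s.
    """

    mu: float = 0.3
    sigma: float = 0.06
    tau: float = 0.08

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be > 0")

    def frozen(self):
        """The scipy frozen distribution (shape K = tau / sigma)."""
        return exponnorm(K=self.tau / self.sigma, loc=self.mu, scale=self.sigma)


@dataclass(frozen=True)
class VirtualParticipant:
    """True per-condition SAT parameters plus the shared RT law."""

    params: Mapping[str, SATParams]
    exg: ExGaussianSpec = ExGaussianSpec()

    def __post_init__(self) -> None:
        if len(self.params) == 0:
            raise ValueError("participant needs at least one condition")
        object.__setattr__(self, "params", dict(self.params))

    @property
    def conditions(self) -> list[str]:
        return list(self.params)


#: Resolution of the cached inverse-CDF tables (points per window).
_INVCDF_POINTS = 2049

_invcdf_cache: dict[tuple, tuple[np.ndarray, np.ndarray] | None] = {}


def _invcdf_table(exg: ExGaussianSpec, soa: float, window: float):
    """Cached (cumulative-mass, rt) table for one truncation window.

    The ex-Gaussian CDF has no closed-form inverse and generic numerical
    inversion is far too slow for simulation loops, so the renormalized
    window CDF is tabulated on a dense grid (exact survival-function
    evaluations; the right tail stays accurate at long SOAs) and inverted by
    linear interpolation.  Returns ``None`` for windows holding numerically
    zero density mass.
    """
    key = (exg.mu, exg.sigma, exg.tau, round(float(soa), 12), round(float(window), 12))
    if key in _invcdf_cache:
        return _invcdf_cache[key]
    dist = exg.frozen()
    xgrid = np.linspace(soa, soa + window, _INVCDF_POINTS)
    sf = dist.sf(xgrid)
    mass = sf[0] - sf[-1]
    if not mass > _MIN_WINDOW_MASS:
        _invcdf_cache[key] = None
        return None
    w = (sf[0] - sf) / mass
    w[0], w[-1] = 0.0, 1.0
    table = (np.maximum.accumulate(w), xgrid)
    _invcdf_cache[key] = table
    return table


def _rt_from_uniform(u, soa, exg: ExGaussianSpec, window: float = 0.2):
    """Inverse-CDF draw from the window-truncated ex-Gaussian.

    Maps uniform variates ``u`` in [0, 1) to response times in
    ``(soa, soa + window]``; ``u`` and ``soa`` broadcast elementwise.
    Windows carrying numerically zero density fall back to a uniform draw on
    the window (logged).
    """
    u = np.asarray(u, dtype=float)
    soa_arr = np.asarray(soa, dtype=float)
    u_b, soa_b = np.broadcast_arrays(u, soa_arr)
    out = np.empty(u_b.shape)
    for s in np.unique(soa_b):
        sel = soa_b == s
        table = _invcdf_table(exg, float(s), window)
        if table is None:
            logger.warning(
                "ex-Gaussian window mass below %.0e at SOA %.4f s; uniform fallback",
                _MIN_WINDOW_MASS, float(s),
            )
            out[sel] = s + u_b[sel] * window
        else:
            out[sel] = np.interp(u_b[sel], *table)
    out = np.clip(out, np.nextafter(soa_b, np.inf), soa_b + window)
    if u.ndim == 0 and soa_arr.ndim == 0:
        return float(out)
    return out


def sample_rt(soa: float, exg: ExGaussianSpec, rng: np.random.Generator,
              window: float = 0.2) -> float:
    """One response-time draw for a trial at ``soa``; always in (soa, soa+window]."""
    if soa < 0:
        raise ValueError("soa must be >= 0")
    return float(_rt_from_uniform(rng.random(), soa, exg, window))


def simulate_response(true_params: SATParams, rt: float,
                      rng: np.random.Generator, eps: float = EPS) -> int:
    """Bernoulli correctness with success probability clamp(psi(true, rt))."""
    p = clamp_probability(evaluate_satf(true_params, rt), eps)
    return int(rng.random() < p)


@dataclass
class SessionConfig:
    """Design of one adaptive session.

    Defaults mirror the standard two-condition flanker protocol: 16 blocks
    of 16 trials per condition (256 trials per condition), 49 candidate SOAs
    from 0 to 1.2 s, uniform prior on the padded hypothesis grid, sum-rule
    selection, and estimate snapshots after every trial.  ``eval_rts``
    defaults to the 49 SOA values treated as response times.
    """

    grid: ParameterGrid = field(default_factory=build_grid)
    soa_design: SOADesign = field(default_factory=SOADesign.default)
    strategy: Strategy = "sum"
    n_blocks: int = 16
    n_per_condition: int = DEFAULT_BLOCK_SIZE
    lam_limit: float = LAM_LIMIT
    eval_rts: np.ndarray | None = None
    snapshot_stride: int = 1
    snapshot_hwci: bool = True
    eps: float = EPS

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_per_condition < 1:
            raise ValueError("n_blocks and n_per_condition must be >= 1")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot_stride must be >= 1")
        if self.eval_rts is None:
            self.eval_rts = np.asarray(self.soa_design.soa_values, dtype=float)
        else:
            self.eval_rts = np.atleast_1d(np.asarray(self.eval_rts, dtype=float))

    @property
    def n_trials_per_condition(self) -> int:
        return self.n_blocks * self.n_per_condition

    @property
    def response_window(self) -> float:
        return self.soa_design.response_window


@dataclass
class ConditionSnapshots:
    """Per-trial estimate trajectories for one condition of one session.

    ``trial_indices`` are 1-based per-condition trial counts; rows of
    ``curves`` / ``hwci`` / ``param_means`` correspond to the posterior
    right after that trial's update.
    """

    trial_indices: np.ndarray
    curves: np.ndarray          # (T, K) predictive accuracy
    hwci: np.ndarray | None     # (T, K) credible half-widths, if recorded
    param_means: np.ndarray     # (T, 3) marginal means (lam, gamma, delta)


@dataclass
class SessionResult:
    """Complete record of one simulated (or replayed) session."""

    trials: pd.DataFrame
    block_soas: np.ndarray
    posteriors: dict[str, PosteriorGrid]
    final: dict[str, EstimationResult]
    snapshots: dict[str, ConditionSnapshots] | None
    config: SessionConfig


def session_streams(seed, n_conditions: int):
    """Expand a seed into per-condition generators plus an ordering stream.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence`, or a
    :class:`numpy.random.Generator` (spawned).  Returns
    ``(condition_rngs, order_rng)``.
    """
    if isinstance(seed, np.random.Generator):
        children = seed.spawn(n_conditions + 1)
        return children[:n_conditions], children[n_conditions]
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    children = seed.spawn(n_conditions + 1)
    rngs = [np.random.default_rng(c) for c in children]
    return rngs[:n_conditions], rngs[n_conditions]


def run_adaptive_session(participant: VirtualParticipant,
                         config: SessionConfig | None = None,
                         seed=0) -> SessionResult:
    """Simulate one full adaptive session.

    Loop per block: select the SOA maximizing expected information gain
    under the current posteriors (the first block uses the uniform prior),
    randomly interleave the conditions' trials, and for each trial sample a
    response time, draw correctness from the true SAT function and update
    that condition's posterior.  Estimate snapshots are recorded every
    ``config.snapshot_stride`` trials per condition.
    """
    if config is None:
        config = SessionConfig()
    conditions = participant.conditions
    cond_rngs, order_rng = session_streams(seed, len(conditions))
    # Pre-drawn uniform table per condition: column 0 drives the RT draw,
    # column 1 the correctness draw, row t the condition's t-th trial.
    uniforms = {
        c: rng.random((config.n_trials_per_condition, 2))
        for c, rng in zip(conditions, cond_rngs)
    }
    posts = {c: init_prior(config.grid) for c in conditions}
    counters = {c: 0 for c in conditions}
    snaps: dict[str, dict[str, list]] = {
        c: {"t": [], "curve": [], "hwci": [], "pm": []} for c in conditions
    }
    eval_tables = get_eval_tables(config.grid, config.eval_rts, config.eps)
    rows = []
    block_soas = np.empty(config.n_blocks)
    window = config.response_window

    for b in range(config.n_blocks):
        plan = select_next_soa(
            [posts[c] for c in conditions], config.soa_design,
            config.strategy, config.n_per_condition, config.eps,
        )
        block_soas[b] = plan.soa
        logger.debug("block %d/%d: selected SOA %.3f s", b + 1, config.n_blocks,
                     plan.soa)
        order = order_rng.permutation(np.repeat(conditions, config.n_per_condition))
        for within, cond in enumerate(order):
            t = counters[cond]
            u_rt, u_resp = uniforms[cond][t]
            rt = float(_rt_from_uniform(u_rt, plan.soa, participant.exg, window))
            p_true = clamp_probability(
                evaluate_satf(participant.params[cond], rt), config.eps
            )
            correct = int(u_resp < p_true)
            posts[cond] = update_trial(
                posts[cond], TrialRecord(cond, plan.soa, rt, correct), config.eps
            )
            counters[cond] = t + 1
            if (t + 1) % config.snapshot_stride == 0 or t + 1 == config.n_trials_per_condition:
                mass = posts[cond].mass
                snaps[cond]["t"].append(t + 1)
                snaps[cond]["curve"].append(eval_tables.mean_curves(mass))
                if config.snapshot_hwci:
                    snaps[cond]["hwci"].append(eval_tables.hwci(mass))
                pm = posterior_mean_params(posts[cond])
                snaps[cond]["pm"].append(pm.as_tuple())
            rows.append((b + 1, within + 1, cond, plan.soa, rt, correct))

    trials = pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)
    snapshots = {
        c: ConditionSnapshots(
            trial_indices=np.asarray(d["t"], dtype=int),
            curves=np.asarray(d["curve"]),
            hwci=np.asarray(d["hwci"]) if config.snapshot_hwci else None,
            param_means=np.asarray(d["pm"]),
        )
        for c, d in snaps.items()
    }
    final = {
        c: estimate(posts[c], config.eval_rts, config.lam_limit, eps=config.eps)
        for c in conditions
    }
    return SessionResult(trials, block_soas, posts, final, snapshots, config)


def run_mcs_session(participant: VirtualParticipant,
                    mcs_soas: Sequence[float] = DEFAULT_MCS_SOAS,
                    repetitions: int = 2,
                    n_per_condition: int = DEFAULT_BLOCK_SIZE,
                    seed=0,
                    window: float = 0.2,
                    eps: float = EPS) -> pd.DataFrame:
    """Simulate a method-of-constant-stimuli session; returns the trial log.

    Each repetition visits every SOA once, in seeded random block order;
    trial generation matches the adaptive sessions but nothing is selected
    adaptively.  Defaults (8 SOAs x 2 repetitions x 16 trials x 2
    conditions) give the conventional 512-trial baseline session.
    """
    if len(mcs_soas) == 0:
        raise ValueError("mcs_soas must be nonempty")
    conditions = participant.conditions
    cond_rngs, order_rng = session_streams(seed, len(conditions))
    n_blocks = len(mcs_soas) * repetitions
    uniforms = {
        c: rng.random((n_blocks * n_per_condition, 2))
        for c, rng in zip(conditions, cond_rngs)
    }
    soa_order = np.concatenate([
        order_rng.permutation(np.asarray(mcs_soas, dtype=float))
        for _ in range(repetitions)
    ])
    counters = {c: 0 for c in conditions}
    rows = []
    for b, soa in enumerate(soa_order):
        order = order_rng.permutation(np.repeat(conditions, n_per_condition))
        for within, cond in enumerate(order):
            t = counters[cond]
            u_rt, u_resp = uniforms[cond][t]
            rt = float(_rt_from_uniform(u_rt, soa, participant.exg, window))
            p_true = clamp_probability(evaluate_satf(participant.params[cond], rt), eps)
            rows.append((b + 1, within + 1, cond, float(soa), rt, int(u_resp < p_true)))
            counters[cond] = t + 1
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)
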