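"""Speed-accuracy tradeoff function and its discretized hypothesis space.

In a response-signal experiment the probability of a correct two-alternative
forced-choice response is modelled as a shifted exponential approach from
chance to an asymptote:

    psi(x) = 0.5 + lam * (1 - exp(-gamma * (x - delta)))    if x > delta
    psi(x) = 0.5                                            if x <= delta

where ``x`` is the response time in seconds, ``lam`` the asymptote above
chance (so maximal accuracy is ``0.5 + lam``), ``gamma`` the rate (1/s) and
``delta`` the intercept time (s) below which performance stays at chance.

Inference runs on a dense Cartesian lattice over (lam, gamma, delta); this
module owns that lattice (:class:`ParameterGrid`), the candidate
stimulus-onset-asynchrony levels (:class:`SOADesign`) and the probability
clamp needed when the lam axis is deliberately padded beyond the theoretical
limit of 0.5 (in which case psi can exceed 1 and is no longer a valid
Bernoulli parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np

#: Default clamp width for probabilities derived from a padded lam axis.
EPS = 1e-6

#: Theoretical upper limit for the asymptote parameter (accuracy <= 1).
LAM_LIMIT = 0.5

#: Padded lam range (extends past the limit; estimates are truncated later).
LAM_RANGE_PADDED = (0.4, 0.55)

#: Unpadded lam range respecting the theoretical limit.
LAM_RANGE_UNPADDED = (0.4, 0.5)

#: Duration of the response window following the response signal (s).
RESPONSE_WINDOW = 0.2


class InvalidConfigError(ValueError):
    """Raised for degenerate grid or design configuration."""


@dataclass(frozen=True)
class SATParams:
    """One condition's (lam, gamma, delta) hypothesis.

    Parameters
    ----------
    lam : float
        Asymptote above chance, dimensionless probability units; > 0.
    gamma : float
        Rate of approach to the asymptote, 1/seconds; > 0.
    delta : float
        Intercept time at which accuracy starts rising, seconds; >= 0.
    """

    lam: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        for name, value in (("lam", self.lam), ("gamma", self.gamma),
                            ("delta", self.delta)):
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lam, self.gamma, self.delta)


def _satf(lam, gamma, delta, rt):
    """Branch-free SAT function on broadcastable array arguments.

    ``-expm1`` keeps precision for small exponents; ``maximum(rt - delta, 0)``
    collapses the below-intercept branch to exactly 0.5.
    """
    return 0.5 + np.asarray(lam) * (
        -np.expm1(-np.asarray(gamma) * np.maximum(np.asarray(rt, float) - delta, 0.0))
    )


def evaluate_satf(params: SATParams, rt):
    """Probability of a correct response at response time ``rt`` (seconds).

    Returns 0.5 for ``rt <= delta`` and
    ``0.5 + lam * (1 - exp(-gamma * (rt - delta)))`` otherwise; the function
    is continuous at ``rt = delta`` and nondecreasing in ``rt``.  Note that a
    padded ``lam > 0.5`` makes the value exceed 1; use
    :func:`clamp_probability` before treating it as a Bernoulli parameter.

    ``rt`` may be a scalar or array; negative or non-finite response times
    are rejected.
    """
    x = np.asarray(rt, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("rt must be finite")
    if np.any(x < 0):
        raise ValueError("rt must be >= 0")
    out = _satf(params.lam, params.gamma, params.delta, x)
    return float(out) if np.isscalar(rt) or x.ndim == 0 else out


def clamp_probability(p, eps: float = EPS):
    """Clamp ``p`` into ``[eps, 1 - eps]`` (idempotent).

    Needed because the padded lam axis lets the SAT function exceed 1.0,
    which would otherwise produce zero or negative Bernoulli likelihoods.
    """
    if not 0 < eps < 0.01:
        raise ValueError(f"eps must lie in (0, 0.01), got {eps}")
    out = np.clip(p, eps, 1.0 - eps)
    return float(out) if np.isscalar(p) else out


def _validated_axis(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise InvalidConfigError(f"{name} axis must be a non-empty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise InvalidConfigError(f"{name} axis must be finite")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise InvalidConfigError(f"{name} axis must be strictly increasing")
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True, eq=False)
class ParameterGrid:
    """Cartesian lattice over (lam, gamma, delta) hypotheses.

    Cells are linearly ordered in C order with lam slowest and delta fastest:
    ``cell = (i_lam * n_gamma + i_gamma) * n_delta + i_delta``.  The flat
    per-cell parameter arrays (:attr:`lam_flat` etc.) follow that ordering and
    are what the posterior engine and stimulus selection vectorize over.
    """

    lam_values: np.ndarray
    gamma_values: np.ndarray
    delta_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lam_values", _validated_axis("lam", self.lam_values))
        object.__setattr__(self, "gamma_values", _validated_axis("gamma", self.gamma_values))
        object.__setattr__(self, "delta_values", _validated_axis("delta", self.delta_values))
        if self.lam_values[0] <= 0 or self.gamma_values[0] <= 0 or self.delta_values[0] < 0:
            raise InvalidConfigError("axis values must satisfy lam > 0, gamma > 0, delta >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.lam_values.size, self.gamma_values.size, self.delta_values.size)

    @property
    def n_cells(self) -> int:
        nl, ng, nd = self.shape
        return nl * ng * nd

    @cached_property
    def _flat_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lam, gam, dlt = np.meshgrid(
            self.lam_values, self.gamma_values, self.delta_values, indexing="ij"
        )
        out = (lam.ravel(), gam.ravel(), dlt.ravel())
        for a in out:
            a.flags.writeable = False
        return out

    @property
    def lam_flat(self) -> np.ndarray:
        return self._flat_axes[0]

    @property
    def gamma_flat(self) -> np.ndarray:
        return self._flat_axes[1]

    @property
    def delta_flat(self) -> np.ndarray:
        return self._flat_axes[2]

    def index_of(self, i_lam: int, i_gamma: int, i_delta: int) -> int:
        """Flat cell index of axis indices (inverse of :meth:`unravel`)."""
        return int(np.ravel_multi_index((i_lam, i_gamma, i_delta), self.shape))

    def unravel(self, index: int) -> tuple[int, int, int]:
        i, j, k = np.unravel_index(index, self.shape)
        return int(i), int(j), int(k)

    def params_at(self, index: int) -> SATParams:
        """The (lam, gamma, delta) triple stored at a flat cell index."""
        i, j, k = self.unravel(index)
        return SATParams(
            float(self.lam_values[i]),
            float(self.gamma_values[j]),
            float(self.delta_values[k]),
        )

    def key(self) -> tuple:
        """Hashable identity used for caching derived lookup tables."""
        return (
            tuple(self.lam_values.tolist()),
            tuple(self.gamma_values.tolist()),
            tuple(self.delta_values.tolist()),
        )


def build_grid(
    lam_range: tuple[float, float] = LAM_RANGE_PADDED,
    n_lam: int = 21,
    gamma_range: tuple[float, float] = (1.0, 30.0),
    n_gamma: int = 30,
    delta_range: tuple[float, float] = (0.02, 0.5),
    n_delta: int = 25,
) -> ParameterGrid:
    """Linearly spaced hypothesis grid including both endpoints of each range.

    Defaults give the 21 x 30 x 25 = 15,750-cell lattice with the padded lam
    axis (0.4-0.55); pass ``lam_range=LAM_RANGE_UNPADDED`` for the variant
    that respects the theoretical asymptote limit.
    """
    axes = []
    for name, (lo, hi), n in (
        ("lam", lam_range, n_lam),
        ("gamma", gamma_range, n_gamma),
        ("delta", delta_range, n_delta),
    ):
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise InvalidConfigError(f"{name} range must be finite")
        if not lo < hi:
            raise InvalidConfigError(f"{name} range must satisfy lower < upper, got ({lo}, {hi})")
        if n < 2:
            raise InvalidConfigError(f"{name} axis needs at least 2 values, got {n}")
        axes.append(np.linspace(lo, hi, n))
    return ParameterGrid(*axes)


@dataclass(frozen=True, eq=False)
class SOADesign:
    """Candidate stimulus-onset asynchronies and the response window.

    The response signal stays on for ``response_window`` seconds, so a trial
    at SOA ``T`` yields a response time in ``(T, T + window]``; the expected
    response time used when planning a block is the window midpoint
    ``x_hat = T + window / 2``.
    """

    soa_values: np.ndarray
    response_window: float = RESPONSE_WINDOW

    def __post_init__(self) -> None:
        arr = np.asarray(self.soa_values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidConfigError("soa_values must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise InvalidConfigError("soa_values must be finite and >= 0")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise InvalidConfigError("soa_values must be strictly increasing")
        if not (math.isfinite(self.response_window) and self.response_window > 0):
            raise InvalidConfigError("response_window must be positive")
        arr.flags.writeable = False
        object.__setattr__(self, "soa_values", arr)

    @property
    def n_soas(self) -> int:
        return self.soa_values.size

    @property
    def expected_rts(self) -> np.ndarray:
        """Per-SOA planning response time ``T + window / 2``."""
        return self.soa_values + self.response_window / 2.0

    def expected_rt(self, soa: float) -> float:
        return float(soa) + self.response_window / 2.0

    @classmethod
    def default(cls) -> "SOADesign":
        """49 linearly spaced SOAs from 0 to 1.2 s (0.025-s steps)."""
        return cls(np.linspace(0.0, 1.2, 49))

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float,
                   response_window: float = RESPONSE_WINDOW) -> "SOADesign":
        n = int(round((hi - lo) / step)) + 1
        return cls(np.linspace(lo, hi, n), response_window)

    def key(self) -> tuple:
        return (tuple(self.soa_values.tolist()), float(self.response_window))


def satf_grid_table(grid: ParameterGrid, rts, eps: float = EPS) -> np.ndarray:
    """Clamped SAT-function values for every grid cell at every ``rt``.

    Returns an ``(n_rt, n_cells)`` array; the workhorse lookup behind
    likelihoods, predictive curves and outcome distributions.
    """
    x = np.atleast_1d(np.asarray(rts, dtype=float))
    psi = _satf(
        grid.lam_flat[np.newaxis, :],
        grid.gamma_flat[np.newaxis, :],
        grid.delta_flat[np.newaxis, :],
        x[:, np.newaxis],
    )
    return np.clip(psi, eps, 1.0 - eps)
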