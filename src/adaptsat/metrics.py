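"""Accuracy, precision, efficiency and agreement measures for SAT estimation.

Accuracy is the mean absolute error (MAE) between estimated and true
accuracy curves over the evaluation grid; the headline form aggregates the
*signed* deviation across runs before taking the absolute value,

    MAE_i = sum_k | sum_j (pc_ijk - pc_true_k) | / (J * K),

so run-level errors of opposite sign cancel and the statistic measures
systematic bias.  The per-run mean absolute deviation ("absolute" form) is
also provided; by the triangle inequality it always dominates the signed
form.  Precision is the credible half-width of the predicted accuracy
(HWCI) averaged over evaluation points and runs; efficiency is the first
trial at which a metric trajectory reaches a threshold; agreement with a
method-of-constant-stimuli (MCS) baseline is the RMSE between adaptive
predictions and binned MCS accuracies at the bins' mean response times.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .model import SATParams, evaluate_satf
from .posterior import PosteriorGrid, predictive_pc_curve

MAE_FORMS = ("signed", "absolute")


@dataclass
class MetricTrajectory:
    """A metric evaluated after successive trials, aggregated over runs."""

    trial_indices: np.ndarray
    values: np.ndarray
    n_runs: int
    n_points: int

    def __post_init__(self) -> None:
        self.trial_indices = np.asarray(self.trial_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.trial_indices.shape != self.values.shape:
            raise ValueError("trial_indices and values must have equal length")
        if self.trial_indices.size == 0:
            raise ValueError("trajectory must be non-empty")
        if np.any(np.diff(self.trial_indices) <= 0):
            raise ValueError("trial indices must be strictly increasing")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("metric values must be finite and >= 0")


def _stacked_snapshots(sessions, condition: str, attr: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack one snapshot array across sessions, checking configs agree."""
    if len(sessions) == 0:
        raise ValueError("need at least one session")
    first = sessions[0].snapshots[condition]
    eval_rts = sessions[0].config.eval_rts
    arrays = []
    for s in sessions:
        snap = s.snapshots[condition]
        if not np.array_equal(snap.trial_indices, first.trial_indices):
            raise ValueError("sessions have mismatched snapshot trial indices")
        if not np.array_equal(s.config.eval_rts, eval_rts):
            raise ValueError("sessions have mismatched evaluation points")
        arr = getattr(snap, attr)
        if arr is None:
            raise ValueError(f"sessions lack recorded {attr!r} snapshots")
        arrays.append(arr)
    return np.stack(arrays), first.trial_indices, eval_rts


def mae_from_deviations(dev: np.ndarray, form: str = "signed") -> np.ndarray:
    """Collapse a (J, T, K) deviation stack to a per-trial MAE vector."""
    if form not in MAE_FORMS:
        raise ValueError(f"form must be one of {MAE_FORMS}, got {form!r}")
    if form == "signed":
        return np.abs(dev.mean(axis=0)).mean(axis=-1)
    return np.abs(dev).mean(axis=0).mean(axis=-1)


def mae_curve(sessions, condition: str, true_params: SATParams,
              form: str = "signed") -> MetricTrajectory:
    """MAE trajectory for one condition over a batch of sessions.

    ``form="signed"`` applies the absolute value outside the across-run
    mean (bias semantics); ``form="absolute"`` is the per-run mean absolute
    deviation.
    """
    curves, trial_idx, eval_rts = _stacked_snapshots(sessions, condition, "curves")
    true_curve = evaluate_satf(true_params, eval_rts)
    vals = mae_from_deviations(curves - true_curve, form)
    return MetricTrajectory(trial_idx, vals, len(sessions), eval_rts.size)


def hwci_curve(sessions, condition: str) -> MetricTrajectory:
    """Mean credible half-width trajectory over runs and evaluation points."""
    hwci, trial_idx, eval_rts = _stacked_snapshots(sessions, condition, "hwci")
    vals = hwci.mean(axis=(0, 2))
    return MetricTrajectory(trial_idx, vals, len(sessions), eval_rts.size)


def trials_to_criterion(traj: MetricTrajectory, threshold: float) -> int | None:
    """First trial index at which the trajectory is at or below ``threshold``.

    Returns ``None`` when the criterion is never reached (report as
    "> N"); no monotonicity is assumed — the first crossing wins even if
    the metric later rises again.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    hits = np.flatnonzero(traj.values <= threshold)
    if hits.size == 0:
        return None
    return int(traj.trial_indices[hits[0]])


def format_trials(result: int | None, n_max: int) -> str:
    """Human-readable trials-to-criterion, with the "> N" sentinel."""
    return f"> {n_max}" if result is None else str(result)


@dataclass
class BinSummary:
    """Per-bin mean response time and accuracy for binned MCS responses."""

    mean_rt: np.ndarray
    pc: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.mean_rt = np.asarray(self.mean_rt, dtype=float)
        self.pc = np.asarray(self.pc, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.mean_rt) < 0):
            raise ValueError("bins must be ordered by mean RT")
        if np.any((self.pc < 0) | (self.pc > 1)):
            raise ValueError("pc must lie in [0, 1]")


def rt_bin_pc(trials, n_bins: int = 8) -> BinSummary:
    """Group trials into equal-count RT bins (fastest to slowest).

    ``trials`` is a trial-log DataFrame (or anything with ``rt`` and
    ``correct`` columns).  When the trial count is not divisible by
    ``n_bins`` the remainder is spread one-per-bin over the earliest bins.
    """
    if isinstance(trials, pd.DataFrame):
        rt = trials["rt"].to_numpy(dtype=float)
        correct = trials["correct"].to_numpy(dtype=float)
    else:
        rt = np.asarray([t.rt for t in trials], dtype=float)
        correct = np.asarray([t.correct for t in trials], dtype=float)
    if rt.size < n_bins:
        raise ValueError(f"need at least {n_bins} trials, got {rt.size}")
    order = np.argsort(rt, kind="stable")
    q, r = divmod(rt.size, n_bins)
    counts = np.full(n_bins, q)
    counts[:r] += 1
    edges = np.concatenate([[0], np.cumsum(counts)])
    mean_rt = np.empty(n_bins)
    pc = np.empty(n_bins)
    for i in range(n_bins):
        sel = order[edges[i]:edges[i + 1]]
        mean_rt[i] = rt[sel].mean()
        pc[i] = correct[sel].mean()
    return BinSummary(mean_rt, pc, counts)


def rmse_adaptive_vs_mcs(bins: BinSummary, adaptive) -> float:
    """Root-mean-square disagreement between adaptive curves and MCS bins.

    ``adaptive`` is either a (J, I) array of per-run predicted accuracies at
    the bins' mean RTs, or a sequence of per-run condition posteriors from
    which those predictions are computed.
    """
    if len(adaptive) and isinstance(adaptive[0], PosteriorGrid):
        preds = np.stack([predictive_pc_curve(p, bins.mean_rt) for p in adaptive])
    else:
        preds = np.atleast_2d(np.asarray(adaptive, dtype=float))
    if preds.shape[1] != bins.mean_rt.size:
        raise ValueError("adaptive predictions do not match the number of bins")
    dev = preds - bins.pc[np.newaxis, :]
    return float(np.sqrt(np.mean(dev ** 2)))
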