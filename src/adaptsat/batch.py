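"""Vectorized engine for running many adaptive sessions in lockstep.

The replication studies need hundreds of independent sessions per
participant x strategy cell with per-trial metric trajectories.  Running
them one by one through :func:`adaptsat.simulate.run_adaptive_session`
would repeat the same grid-shaped work once per run, so this engine keeps
all runs' posteriors in a single ``(n_runs, n_cells)`` matrix and advances
them trial by trial together: likelihood updates, information-gain scans
and predictive-curve snapshots become matrix contractions against the
cached lookup tables.

Each run draws from its own RNG substream — run ``r`` of master seed ``m``
uses ``SeedSequence(m, spawn_key=(r,))``, expanded exactly as in
:func:`~adaptsat.simulate.session_streams` — so any single run of a batch
can be reproduced in isolation by the plain per-session path, and results
do not depend on how runs are grouped into batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._tables import get_design_tables, get_eval_tables
from .metrics import MetricTrajectory
from .model import SATParams, evaluate_satf
from .posterior import NumericalError
from .simulate import SessionConfig, VirtualParticipant, _rt_from_uniform
from .selection import resolve_strategy

DEFAULT_PARAM_CHECKPOINTS = (16, 64, 256)


def _resolve_trials(spec, n_trials: int) -> np.ndarray:
    """Normalize a trial-subset spec ("all" | stride int as "every" | list | None)."""
    if spec is None:
        return np.array([n_trials], dtype=int)
    if isinstance(spec, str):
        if spec == "all":
            return np.arange(1, n_trials + 1)
        raise ValueError(f"unknown trial spec {spec!r}")
    arr = np.unique(np.asarray(spec, dtype=int))
    if arr.size and (arr[0] < 1 or arr[-1] > n_trials):
        raise ValueError("trial indices out of session range")
    return arr


def strided_trials(n_trials: int, stride: int) -> np.ndarray:
    """Every ``stride``-th trial plus the final one."""
    idx = np.arange(stride, n_trials + 1, stride)
    if idx.size == 0 or idx[-1] != n_trials:
        idx = np.append(idx, n_trials)
    return idx


@dataclass
class ConditionBatchResult:
    """Aggregated trajectories for one condition across all runs."""

    condition: str
    true_params: SATParams
    eval_rts: np.ndarray
    true_curve: np.ndarray              # (K,) accuracy from the true params
    n_runs: int
    trial_indices: np.ndarray           # (T,) 1-based
    mean_curve_by_trial: np.ndarray     # (T, K) across-run mean prediction
    absdev_trials: np.ndarray           # (Ta,) trials with per-run |dev| recorded
    sum_absdev: np.ndarray              # (Ta, K) summed over runs
    hwci_trials: np.ndarray             # (Th,)
    hwci_mean: np.ndarray               # (Th,) mean over runs and points
    hwci_run_means: np.ndarray          # (Th, J) per-run mean over points
    param_mean_by_trial: np.ndarray     # (T, 3) across-run mean marginal means
    param_checkpoints: np.ndarray       # (Tc,)
    param_runs: np.ndarray              # (J, Tc, 3) per-run marginal means
    final_mass: np.ndarray | None = None

    def mae_trajectory(self, form: str = "signed") -> MetricTrajectory:
        """Per-trial MAE; the "absolute" form only covers ``absdev_trials``."""
        if form == "signed":
            dev = self.mean_curve_by_trial - self.true_curve
            vals = np.abs(dev).mean(axis=-1)
            return MetricTrajectory(self.trial_indices, vals, self.n_runs,
                                    self.eval_rts.size)
        if form == "absolute":
            vals = (self.sum_absdev / self.n_runs).mean(axis=-1)
            return MetricTrajectory(self.absdev_trials, vals, self.n_runs,
                                    self.eval_rts.size)
        raise ValueError(f"unknown MAE form {form!r}")

    def hwci_trajectory(self) -> MetricTrajectory:
        return MetricTrajectory(self.hwci_trials, self.hwci_mean, self.n_runs,
                                self.eval_rts.size)


@dataclass
class BatchResult:
    """All-conditions result of one lockstep batch."""

    conditions: dict[str, ConditionBatchResult]
    block_soas: np.ndarray              # (J, n_blocks)
    n_runs: int
    master_seed: int
    config: SessionConfig = field(repr=False)


def _draw_uniform_tables(master_seed: int, n_runs: int, n_conditions: int,
                         n_trials: int) -> list[np.ndarray]:
    """Per-condition (J, T, 2) uniform tables matching the session streams."""
    tables = [np.empty((n_runs, n_trials, 2)) for _ in range(n_conditions)]
    for r in range(n_runs):
        ss = np.random.SeedSequence(master_seed, spawn_key=(r,))
        children = ss.spawn(n_conditions + 1)  # last child = interleave order
        for c in range(n_conditions):
            tables[c][r] = np.random.default_rng(children[c]).random((n_trials, 2))
    return tables


def run_adaptive_batch(participant: VirtualParticipant,
                       config: SessionConfig,
                       n_runs: int,
                       master_seed: int,
                       absdev_trials="all",
                       hwci_trials=None,
                       param_checkpoints: Sequence[int] = DEFAULT_PARAM_CHECKPOINTS,
                       record_final_mass: bool = False) -> BatchResult:
    """Run ``n_runs`` adaptive sessions in lockstep and aggregate trajectories.

    Parameters
    ----------
    absdev_trials, hwci_trials :
        Which per-condition trial indices get the expensive per-run
        statistics: ``"all"``, an explicit index list, or ``None``
        (final trial only); ``hwci_trials`` may also be a dict mapping
        condition name to such a spec.  The across-run mean predictive
        curve and the marginal-mean trajectory are always recorded at
        every trial.
    param_checkpoints :
        Trials at which per-run marginal posterior means are kept (for
        parameter-recovery analyses).
    """
    conditions = participant.conditions
    n_cond = len(conditions)
    grid = config.grid
    design = config.soa_design
    n_trials = config.n_trials_per_condition
    n_per = config.n_per_condition
    strategy_idx = resolve_strategy(config.strategy, n_cond)

    absdev_idx = _resolve_trials(absdev_trials, n_trials)
    if isinstance(hwci_trials, dict):
        hwci_idx = [_resolve_trials(hwci_trials.get(c), n_trials) for c in conditions]
    else:
        hwci_idx = [_resolve_trials(hwci_trials, n_trials)] * n_cond
    cp_idx = np.asarray([t for t in param_checkpoints if t <= n_trials], dtype=int)

    dtab = get_design_tables(grid, design, n_per, config.eps)
    etab = get_eval_tables(grid, config.eval_rts, config.eps)
    K = etab.eval_rts.size
    C = grid.n_cells
    nl = grid.lam_values.size
    n_gd = C // nl
    # (gamma, delta) sub-lattice shared by every lam slice (lam varies slowest)
    gamma_gd = grid.gamma_flat[:n_gd]
    delta_gd = grid.delta_flat[:n_gd]
    lam = grid.lam_values
    lo, hi = config.eps, 1.0 - config.eps

    uniforms = _draw_uniform_tables(master_seed, n_runs, n_cond, n_trials)
    W = [np.full((n_runs, C), 1.0 / C) for _ in range(n_cond)]
    axes_mat = np.stack([grid.lam_flat, grid.gamma_flat, grid.delta_flat], axis=1)

    true_curves = [
        evaluate_satf(participant.params[c], etab.eval_rts) for c in conditions
    ]

    sum_curve = [np.zeros((n_trials, K)) for _ in range(n_cond)]
    sum_absdev = [np.zeros((absdev_idx.size, K)) for _ in range(n_cond)]
    hwci_mean = [np.zeros(idx.size) for idx in hwci_idx]
    hwci_runs = [np.zeros((idx.size, n_runs)) for idx in hwci_idx]
    pm_by_trial = [np.zeros((n_trials, 3)) for _ in range(n_cond)]
    param_runs = [np.zeros((n_runs, cp_idx.size, 3)) for _ in range(n_cond)]
    block_soas = np.empty((n_runs, config.n_blocks))

    absdev_pos = {t: i for i, t in enumerate(absdev_idx)}
    hwci_pos = [{t: i for i, t in enumerate(idx)} for idx in hwci_idx]
    cp_pos = {t: i for i, t in enumerate(cp_idx)}

    for b in range(config.n_blocks):
        # --- select each run's SOA from its own posterior state ---------
        if strategy_idx is None:
            profile = dtab.gain_profile(W[0])
            for ci in range(1, n_cond):
                profile += dtab.gain_profile(W[ci])
        else:
            profile = dtab.gain_profile(W[strategy_idx])
        # same tie rule as select_next_soa: earliest SOA within 1e-12 of max
        soa_i = np.argmax(profile >= profile.max(axis=1, keepdims=True) - 1e-12,
                          axis=1)
        soas = design.soa_values[soa_i]
        block_soas[:, b] = soas

        for ci, cond in enumerate(conditions):
            tp = participant.params[cond]
            Wc = W[ci]
            W3 = Wc.reshape(n_runs, nl, n_gd)
            for t_local in range(n_per):
                t = b * n_per + t_local  # 0-based per-condition trial index
                u_rt = uniforms[ci][:, t, 0]
                u_resp = uniforms[ci][:, t, 1]
                rts = _rt_from_uniform(u_rt, soas, participant.exg,
                                       design.response_window)
                p_true = np.clip(evaluate_satf(tp, rts), lo, hi)
                correct = u_resp < p_true
                # per-run likelihood over the grid, factored as lam x (gamma, delta)
                g = -np.expm1(-gamma_gd[np.newaxis, :]
                              * np.maximum(rts[:, np.newaxis] - delta_gd, 0.0))
                psi = np.clip(0.5 + lam[np.newaxis, :, np.newaxis]
                              * g[:, np.newaxis, :], lo, hi)
                like = np.where(correct[:, np.newaxis, np.newaxis], psi, 1.0 - psi)
                W3 *= like
                totals = W3.sum(axis=(1, 2))
                if not np.all(totals > 0.0):
                    raise NumericalError("batch update produced zero-mass run")
                W3 /= totals[:, np.newaxis, np.newaxis]

                trial_no = t + 1
                mass_sum = Wc.sum(axis=0)
                pm_by_trial[ci][t] = (mass_sum @ axes_mat) / n_runs
                ad = absdev_pos.get(trial_no)
                if ad is not None:
                    curves = etab.mean_curves(Wc)  # (J, K)
                    sum_curve[ci][t] = curves.sum(axis=0)
                    sum_absdev[ci][ad] = np.abs(curves - true_curves[ci]).sum(axis=0)
                else:
                    sum_curve[ci][t] = etab.mean_curves(mass_sum)
                hw = hwci_pos[ci].get(trial_no)
                if hw is not None:
                    hwci_kj = etab.hwci(Wc)  # (J, K)
                    run_means = hwci_kj.mean(axis=1)
                    hwci_runs[ci][hw] = run_means
                    hwci_mean[ci][hw] = run_means.mean()
                cp = cp_pos.get(trial_no)
                if cp is not None:
                    param_runs[ci][:, cp, :] = Wc @ axes_mat

    results = {}
    for ci, cond in enumerate(conditions):
        results[cond] = ConditionBatchResult(
            condition=cond,
            true_params=participant.params[cond],
            eval_rts=etab.eval_rts,
            true_curve=true_curves[ci],
            n_runs=n_runs,
            trial_indices=np.arange(1, n_trials + 1),
            mean_curve_by_trial=sum_curve[ci] / n_runs,
            absdev_trials=absdev_idx,
            sum_absdev=sum_absdev[ci],
            hwci_trials=hwci_idx[ci],
            hwci_mean=hwci_mean[ci],
            hwci_run_means=hwci_runs[ci],
            param_mean_by_trial=pm_by_trial[ci],
            param_checkpoints=cp_idx,
            param_runs=param_runs[ci],
            final_mass=W[ci].copy() if record_final_mass else None,
        )
    return BatchResult(results, block_soas, n_runs, master_seed, config)
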