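"""End-to-end regeneration of the two simulation studies, plus offline refits.

Study 1 compares three SOA-selection strategies for two concurrently
estimated flanker conditions: selection by the congruent condition's
information gain alone ("1"), by the incongruent condition's alone ("2"),
and by the sum over conditions ("sum").  Study 2 compares the hypothesis
grid that respects the theoretical asymptote limit (lam in 0.4-0.5,
"without" adjustment) against the padded grid (0.4-0.55) whose reported
asymptote estimates are truncated at 0.5 ("with" adjustment), for a
mid-range and a near-ceiling participant.

Every (participant, strategy-or-variant) cell runs ``n_runs`` independent
adaptive sessions through the lockstep batch engine and reports endpoint
accuracy (MAE), precision (HWCI) and trials-to-criterion.  Cell seeds are
derived from the master seed by a counter scheme, so cells and runs are
independent and individually reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .batch import BatchResult, run_adaptive_batch, strided_trials
from .metrics import trials_to_criterion
from .model import (
    LAM_RANGE_PADDED,
    LAM_RANGE_UNPADDED,
    SATParams,
    SOADesign,
    build_grid,
)
from .posterior import (
    PosteriorGrid,
    TrialRecord,
    estimate,
    init_prior,
    update_trial,
)
from .simulate import (
    SessionConfig,
    TRIAL_LOG_COLUMNS,
    VirtualParticipant,
)

#: Accuracy criterion (MAE threshold) for trials-to-criterion.
MAE_CRITERION = 0.010
#: Precision criterion (HWCI threshold) for trials-to-criterion.
HWCI_CRITERION = 0.020


def _vp(cong: tuple, incong: tuple) -> VirtualParticipant:
    return VirtualParticipant({
        "congruent": SATParams(*cong),
        "incongruent": SATParams(*incong),
    })


#: Study-1 virtual participants: increasingly extreme incongruent parameters.
SIM1_PARTICIPANTS: Mapping[str, VirtualParticipant] = {
    "P1": _vp((0.45, 25.0, 0.20), (0.45, 25.0, 0.30)),
    "P2": _vp((0.45, 25.0, 0.20), (0.45, 25.0, 0.45)),
    "P3": _vp((0.45, 25.0, 0.20), (0.45, 5.0, 0.45)),
}

#: Study-2 virtual participants: mid-range vs near-ceiling asymptote.
SIM2_PARTICIPANTS: Mapping[str, VirtualParticipant] = {
    "P1": _vp((0.45, 25.0, 0.20), (0.45, 25.0, 0.30)),
    "P2": _vp((0.495, 25.0, 0.20), (0.495, 25.0, 0.30)),
}

#: lam-axis ranges for the two Study-2 variants.
VARIANT_LAM_RANGES = {"without": LAM_RANGE_UNPADDED, "with": LAM_RANGE_PADDED}


@dataclass
class StudySpec:
    """Configuration of one replication study.

    ``hwci_stride`` controls how often per-run credible half-widths are
    recorded (1 = every trial, the full-fidelity default; larger strides
    trade trials-to-criterion resolution for speed; ``None`` records the
    endpoint only and leaves the HWCI trials-to-criterion column empty).
    ``mae_form`` selects the MAE aggregation (see
    :mod:`adaptsat.metrics`).
    """

    participants: Mapping[str, VirtualParticipant]
    strategies: Sequence[str] = ("1", "2", "sum")
    variants: Sequence[str] = ("without", "with")
    n_runs: int = 1000
    master_seed: int = 0
    n_blocks: int = 16
    n_per_condition: int = 16
    soa_design: SOADesign = field(default_factory=SOADesign.default)
    hwci_stride: int | None = 1
    mae_form: str = "signed"

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.n_per_condition


def cell_seed(master_seed: int, *indices: int) -> int:
    """Deterministic sub-seed for one study cell (counter scheme, < 2**31)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(indices))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _hwci_trials(spec: StudySpec):
    if spec.hwci_stride is None:
        return None
    return strided_trials(spec.n_trials, spec.hwci_stride)


def run_study_cell(participant: VirtualParticipant, spec: StudySpec,
                   strategy: str, lam_range: tuple[float, float],
                   seed: int) -> BatchResult:
    """One (participant, strategy, grid-variant) batch of adaptive sessions."""
    config = SessionConfig(
        grid=build_grid(lam_range=lam_range),
        soa_design=spec.soa_design,
        strategy=strategy,
        n_blocks=spec.n_blocks,
        n_per_condition=spec.n_per_condition,
    )
    return run_adaptive_batch(
        participant, config, spec.n_runs, seed,
        absdev_trials="all", hwci_trials=_hwci_trials(spec),
    )


#: Trial checkpoints reported in the summary tables.
TABLE_CHECKPOINTS = (32, 64, 128, 256)


def summarize_cell(batch: BatchResult, spec: StudySpec, **labels) -> list[dict]:
    """Checkpoint metrics and trials-to-criterion for each condition of a cell."""
    rows = []
    n_trials = spec.n_trials
    for cond, res in batch.conditions.items():
        mae_traj = res.mae_trajectory(spec.mae_form)
        mae_alt_end = float((res.sum_absdev[-1] / res.n_runs).mean())
        hwci_traj = res.hwci_trajectory()
        has_hwci_traj = spec.hwci_stride is not None
        row = dict(labels)
        row.update({
            "condition": cond,
            "mae": float(mae_traj.values[-1]),
            "mae_alt": mae_alt_end,
            "hwci": float(hwci_traj.values[-1]),
        })
        for cp in TABLE_CHECKPOINTS:
            in_mae = np.flatnonzero(mae_traj.trial_indices == cp)
            row[f"mae_{cp}"] = (float(mae_traj.values[in_mae[0]])
                                if in_mae.size else np.nan)
            in_hw = np.flatnonzero(hwci_traj.trial_indices == cp)
            row[f"hwci_{cp}"] = (float(hwci_traj.values[in_hw[0]])
                                 if in_hw.size else np.nan)
        row.update({
            "trials_mae": trials_to_criterion(mae_traj, MAE_CRITERION),
            "trials_hwci": (trials_to_criterion(hwci_traj, HWCI_CRITERION)
                            if has_hwci_traj else None),
            "n_runs": res.n_runs,
            "n_trials": n_trials,
        })
        rows.append(row)
    return rows


def replicate_simulation1(spec: StudySpec | None = None,
                          lam_range: tuple[float, float] = LAM_RANGE_UNPADDED,
                          return_batches: bool = False):
    """Strategy comparison across the Study-1 participants.

    Returns a table with one row per (strategy, participant, condition);
    with ``return_batches=True`` also the underlying :class:`BatchResult`
    per cell, keyed ``(strategy, participant)``.
    """
    if spec is None:
        spec = StudySpec(participants=SIM1_PARTICIPANTS)
    rows, batches = [], {}
    for si, strategy in enumerate(spec.strategies):
        for pi, (name, vp) in enumerate(spec.participants.items()):
            seed = cell_seed(spec.master_seed, 1, si, pi)
            batch = run_study_cell(vp, spec, strategy, lam_range, seed)
            batches[(strategy, name)] = batch
            rows.extend(summarize_cell(batch, spec,
                                       strategy=strategy, participant=name))
    table = pd.DataFrame(rows)
    return (table, batches) if return_batches else table


def replicate_simulation2(spec: StudySpec | None = None,
                          strategy: str = "sum",
                          return_batches: bool = False):
    """Grid-padding comparison (with/without lam adjustment) for Study 2."""
    if spec is None:
        spec = StudySpec(participants=SIM2_PARTICIPANTS)
    rows, batches = [], {}
    for vi, variant in enumerate(spec.variants):
        lam_range = VARIANT_LAM_RANGES[variant]
        for pi, (name, vp) in enumerate(spec.participants.items()):
            seed = cell_seed(spec.master_seed, 2, vi, pi)
            batch = run_study_cell(vp, spec, strategy, lam_range, seed)
            batches[(variant, name)] = batch
            rows.extend(summarize_cell(batch, spec,
                                       variant=variant, participant=name))
    table = pd.DataFrame(rows)
    return (table, batches) if return_batches else table


def estimate_from_log(trial_log: pd.DataFrame,
                      config: SessionConfig | None = None) -> dict:
    """Replay a recorded trial log through fresh posteriors, per condition.

    Rows are applied in recorded order; a response time outside its trial's
    response window raises a warning but the row is retained.  An empty log
    yields the uniform-prior estimates (grid midpoints).
    """
    if config is None:
        config = SessionConfig()
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in trial_log.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    window = config.response_window
    posts: dict[str, PosteriorGrid] = {}
    for i, row in enumerate(trial_log.itertuples(index=False)):
        try:
            trial = TrialRecord(str(row.condition), float(row.soa),
                                float(row.rt), int(row.correct))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed trial log row {i + 1}: {exc}") from exc
        if not trial.soa <= trial.rt <= trial.soa + window:
            warnings.warn(
                f"row {i + 1}: rt {trial.rt:.4f} outside the response window "
                f"[{trial.soa:.4f}, {trial.soa + window:.4f}]; row retained",
                stacklevel=2,
            )
        post = posts.get(trial.condition)
        if post is None:
            post = init_prior(config.grid)
        posts[trial.condition] = update_trial(post, trial, config.eps)
    if not posts:  # empty log: report the uniform-prior estimate
        posts["prior"] = init_prior(config.grid)
    return {
        cond: estimate(post, config.eval_rts, config.lam_limit, eps=config.eps)
        for cond, post in posts.items()
    }
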