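"""Reading and writing trial logs, design configs and estimation results.

Trial logs are plain delimited text (CSV) with the header columns
``block, trial, condition, soa, rt, correct``; all times are in seconds and
``correct`` is 0/1.  Design configuration is YAML; estimation results are
serialized to JSON with enough grid metadata to re-create the posterior
setup.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    EPS,
    LAM_LIMIT,
    InvalidConfigError,
    SATParams,
    SOADesign,
    build_grid,
)
from .posterior import EstimationResult
from .simulate import (
    ExGaussianSpec,
    SessionConfig,
    TRIAL_LOG_COLUMNS,
    VirtualParticipant,
)

_NUMERIC_COLUMNS = ("block", "trial", "soa", "rt", "correct")


def write_trial_log(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial log, naming the offending row on errors."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} is missing columns: {missing}")
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & df[col].notna())
        if bad.size or coerced.isna().any():
            row = int((bad[0] if bad.size else np.flatnonzero(coerced.isna())[0]) + 2)
            raise ValueError(f"trial log {path}: unparseable {col!r} at line {row}")
        df[col] = coerced
    if not df["correct"].isin((0, 1)).all():
        row = int(np.flatnonzero(~df["correct"].isin((0, 1)))[0] + 2)
        raise ValueError(f"trial log {path}: correct must be 0/1 at line {row}")
    return df


def _axis_from_config(section, name: str) -> tuple[tuple[float, float], int]:
    try:
        return (float(section["min"]), float(section["max"])), int(section["n"])
    except (KeyError, TypeError, ValueError) as exc:
        raise InvalidConfigError(f"bad {name} axis spec: {section!r}") from exc


def session_config_from_dict(cfg: dict) -> SessionConfig:
    """Build a :class:`SessionConfig` from a parsed design-config mapping."""
    grid_cfg = cfg.get("grid", {})
    kwargs = {}
    for axis in ("lam", "gamma", "delta"):
        if axis in grid_cfg:
            rng, n = _axis_from_config(grid_cfg[axis], axis)
            kwargs[f"{axis}_range"] = rng
            kwargs[f"n_{axis}"] = n
    grid = build_grid(**kwargs)
    window = float(cfg.get("response_window", 0.2))
    soa_cfg = cfg.get("soa")
    if soa_cfg is None:
        design = SOADesign(np.linspace(0.0, 1.2, 49), window)
    else:
        (lo, hi), n = _axis_from_config(soa_cfg, "soa")
        design = SOADesign(np.linspace(lo, hi, n), window)
    block = cfg.get("block", {})
    return SessionConfig(
        grid=grid,
        soa_design=design,
        strategy=str(cfg.get("strategy", "sum")),
        n_blocks=int(block.get("n_blocks", 16)),
        n_per_condition=int(block.get("n_per_condition", 16)),
        lam_limit=float(cfg.get("lam_limit", LAM_LIMIT)),
        eps=float(cfg.get("eps", EPS)),
    )


def load_session_config(path) -> SessionConfig:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return session_config_from_dict(cfg)


def load_participant(path) -> VirtualParticipant:
    """Participant YAML: per-condition (lam, gamma, delta) plus RT law."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    conditions = cfg.get("conditions")
    if not conditions:
        raise InvalidConfigError(f"participant file {path} has no conditions")
    params = {
        str(name): SATParams(float(p["lam"]), float(p["gamma"]), float(p["delta"]))
        for name, p in conditions.items()
    }
    exg_cfg = cfg.get("exgaussian", {})
    exg = ExGaussianSpec(
        mu=float(exg_cfg.get("mu", 0.3)),
        sigma=float(exg_cfg.get("sigma", 0.06)),
        tau=float(exg_cfg.get("tau", 0.08)),
    )
    return VirtualParticipant(params, exg)


def _params_dict(p: SATParams) -> dict:
    return {"lam": p.lam, "gamma": p.gamma, "delta": p.delta}


def estimation_results_to_dict(results: dict[str, EstimationResult],
                               config: SessionConfig) -> dict:
    grid = config.grid
    return {
        "grid": {
            "lam": grid.lam_values.tolist(),
            "gamma": grid.gamma_values.tolist(),
            "delta": grid.delta_values.tolist(),
        },
        "lam_limit": config.lam_limit,
        "conditions": {
            cond: {
                "raw_means": _params_dict(r.raw_means),
                "reported_params": _params_dict(r.reported_params),
                "eval_rts": r.eval_rts.tolist(),
                "mean_curve": r.mean_curve.tolist(),
                "hwci_per_point": r.hwci_per_point.tolist(),
                "mean_hwci": r.mean_hwci,
            }
            for cond, r in results.items()
        },
    }


def save_estimation_results(results: dict[str, EstimationResult],
                            config: SessionConfig, path) -> None:
    Path(path).write_text(json.dumps(estimation_results_to_dict(results, config),
                                     indent=2))
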