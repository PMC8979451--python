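"""Tabular readers/writers, configuration, seeding and the pipeline runner.

All interchange is comma-separated text with a mandatory header; angles are
always signed degrees.  The trial table columns are fixed::

    participant_id, trial_index, block_index, clamp_deg, jump_deg,
    jump_event, feedback_type, hand_angle_deg[, excluded]

Every stochastic stage derives its seed deterministically from the master
seed via ``numpy.random.SeedSequence([master_seed, stage_tag])`` with a
fixed per-stage tag (:func:`stage_seed`), so any stage can be re-run in
isolation and reproduce its output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import analyze
from .fit import FitResult, compare_models, derived_quantities, fit_all_models, bootstrap_ci
from .models import ModelParams, ModelSpec
from .schedules import generate_schedule, validate_schedule
from .simulate import SimConfig, default_generative_params, simulate_cohort

__all__ = [
    "REQUIRED_TRIAL_COLUMNS",
    "RunConfig",
    "read_trials",
    "write_trials",
    "read_condition_means",
    "write_condition_means",
    "fit_result_to_dict",
    "stage_seed",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

REQUIRED_TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "block_index",
    "clamp_deg",
    "jump_deg",
    "jump_event",
    "feedback_type",
    "hand_angle_deg",
]

_ANGLE_COLUMNS = ["clamp_deg", "jump_deg", "hand_angle_deg"]

#: fixed stage tags for seed derivation (order is part of the format)
_STAGE_TAGS = {"schedule": 1, "simulate": 2, "analyze": 3, "fit": 4, "bootstrap": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    try:
        tag = _STAGE_TAGS[stage]
    except KeyError:
        raise ValueError(
            f"unknown stage {stage!r}; expected one of {sorted(_STAGE_TAGS)}"
        ) from None
    return int(np.random.SeedSequence([int(master_seed), tag]).generate_state(1)[0] % (2**31))


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read a trial table, validating columns and angle values.

    Unknown columns are preserved.  A missing required column raises a
    ``ValueError`` naming it; a non-numeric angle names the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing required column(s): {missing}")
    for col in _ANGLE_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at data row {row} of {path}"
            )
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna())[0])
            raise ValueError(f"missing value in column {col!r} at data row {row} of {path}")
        df[col] = parsed.astype(float)
    df["jump_event"] = df["jump_event"].astype(bool)
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)


def write_condition_means(means: pd.DataFrame, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    means.to_csv(path, index=False)


def read_condition_means(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["clamp_mag", "jump_rel", "jump_event", "mean"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"condition-means table missing column(s): {missing}")
    df["jump_event"] = df["jump_event"].astype(bool)
    if "feedback_present" in df.columns:
        df["feedback_present"] = df["feedback_present"].astype(bool)
    return df


def fit_result_to_dict(result: FitResult) -> dict:
    """JSON-serializable summary of a fit."""
    return {
        "model_id": result.model_id,
        "free_params": result.free_values,
        "u0": {str(k): v for k, v in result.params.u0.items()},
        "sse": result.sse,
        "r2": result.r2,
        "aic": result.aic,
        "k": result.k,
        "n_points": result.n_points,
        "n_starts": result.n_starts,
        "best_start_index": result.best_start_index,
        "converged": result.converged,
        "composition": result.composition,
        "no_jump_means": {str(k): v for k, v in result.no_jump_means.items()},
    }


# ---------------------------------------------------------------------------
# run configuration + pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML round-trippable)."""

    experiments: list[str] = field(
        default_factory=lambda: ["exp4a", "exp4b", "exp4c", "exp4d"]
    )
    model_id: str = "distracted_spe_te"
    free_params: dict[str, float] = field(
        default_factory=lambda: {"c_j": 0.84, "sigma_d": 11.8, "beta_te": 0.02}
    )
    u0_composition: str = "constrained"
    noise_sd: float = 0.15
    retention: float = 1.0
    n_participants: int = 210       # split as evenly as possible across designs
    between_subject_sd: float = 0.1
    n_starts: int = 10
    weighting: Optional[str] = None
    bootstrap_B: int = 0            # 0 disables the bootstrap stage
    seed: int = 0
    out_dir: str = "dualerror_run"
    log_level: str = "INFO"

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _split_participants(n: int, k: int) -> list[int]:
    base = n // k
    out = [base + (1 if i < n % k else 0) for i in range(k)]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute schedule -> simulate -> analyze -> fit -> compare -> derived.

    Writes all artifacts under ``config.out_dir`` plus a manifest recording
    seeds and the config hash.  Returns a dict of in-memory artifacts.
    On error, a ``.partial`` marker file is left in the output directory.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    partial = out_dir / ".partial"
    partial.write_text("pipeline in progress or failed\n")
    stage = "setup"
    try:
        spec = ModelSpec.from_id(config.model_id)

        stage = "schedule"
        sched_seed = stage_seed(config.seed, "schedule")
        schedules = {
            exp: generate_schedule(exp, seed=sched_seed) for exp in config.experiments
        }
        for exp, sched in schedules.items():
            report = validate_schedule(sched)
            if not report.ok:
                raise RuntimeError(f"schedule {exp} violates design: {report.violations}")
            sched.to_csv(out_dir / f"schedule_{exp}.csv")

        stage = "simulate"
        sim_seed = stage_seed(config.seed, "simulate")
        counts = _split_participants(config.n_participants, len(config.experiments))
        frames = []
        offset = 0
        for (exp, sched), n_p in zip(schedules.items(), counts):
            params = default_generative_params(spec, exp, **config.free_params)
            sim = SimConfig(
                spec=spec, params=params, noise_sd=config.noise_sd,
                retention=config.retention, n_participants=n_p,
                between_subject_sd=config.between_subject_sd,
                seed=int(np.random.SeedSequence([sim_seed, offset]).generate_state(1)[0] % (2**31)),
            )
            cohort = simulate_cohort(sched, sim)
            cohort["participant_id"] = [
                f"{exp}_{pid}" for pid in cohort["participant_id"]
            ]
            frames.append(cohort)
            offset += 1
        trials = pd.concat(frames, ignore_index=True)
        write_trials(trials, out_dir / "cohort.csv")

        stage = "analyze"
        flagged = analyze.flag_outliers(trials)
        deltas = analyze.normalize_signs(analyze.compute_deltas(flagged))
        per_medians, means = analyze.condition_medians(deltas)
        write_condition_means(means, out_dir / "means.csv")
        n_excluded = int(flagged["excluded"].sum())

        stage = "fit"
        fits = fit_all_models(
            means, n_starts=config.n_starts, seed=stage_seed(config.seed, "fit"),
            composition=config.u0_composition, weighting=config.weighting,
        )
        comparison = compare_models(list(fits.values()))
        best = fits[comparison.best_model_id]
        no_jump = best.no_jump_means
        derived = (
            derived_quantities(best, no_jump)
            if best.spec.family == "distracted" and best.spec.include_te
            else None
        )

        stage = "bootstrap"
        boot = None
        if config.bootstrap_B > 0:
            boot = bootstrap_ci(
                flagged, spec, B=config.bootstrap_B,
                seed=stage_seed(config.seed, "bootstrap"),
                n_starts=config.n_starts, composition=config.u0_composition,
            )
            boot.samples.to_csv(out_dir / "bootstrap_samples.csv", index=False)

        stage = "report"
        report_obj = {
            "fits": {mid: fit_result_to_dict(f) for mid, f in fits.items()},
            "ranking": comparison.table.to_dict(orient="records"),
            "best_model": comparison.best_model_id,
            "derived_quantities": derived,
            "counts": {
                "trials": int(len(trials)),
                "excluded": n_excluded,
                "delta_pairs": int(len(deltas)),
                "participants": int(trials["participant_id"].nunique()),
            },
            "bootstrap": None if boot is None else {
                "B": boot.B, "n_failed": boot.n_failed,
                "ci": {k: list(v) for k, v in boot.ci.items()},
                "mean": boot.mean, "sd": boot.sd,
            },
        }
        (out_dir / "report.json").write_text(json.dumps(report_obj, indent=2))
        manifest = {
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_TAGS},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    partial.unlink(missing_ok=True)
    return {
        "schedules": schedules,
        "trials": trials,
        "means": means,
        "per_participant_medians": per_medians,
        "fits": fits,
        "comparison": comparison,
        "derived": derived,
        "bootstrap": boot,
        "report": report_obj,
    }
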