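"""Model-free trial-level analysis pipeline.

Steps, mirroring standard practice for trial-by-trial clamp designs:

1. :func:`flag_outliers` -- drop reaches deviating > 3 SD from a moving
   5-trial window (attentional lapses, wrong-target reaches).
2. :func:`compute_deltas` -- change in hand angle from trial n to n+1,
   attributed to trial n's perturbation condition.
3. :func:`normalize_signs` -- collapse mirror-image perturbations into a
   single frame where positive deltas mean recalibration in the expected
   direction (away from the clamp; along the jump on TE-only trials).
4. :func:`condition_medians` -- per-participant condition medians, then
   group mean +/- SEM across participants.
5. :func:`participant_slopes` -- per-participant OLS of delta on signed
   perturbation size (clamp trials and TE-only trials separately), with
   group-level one-sample t-tests of the mean slopes against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import normalize_condition

__all__ = [
    "AnalysisError",
    "flag_outliers",
    "compute_deltas",
    "normalize_signs",
    "condition_medians",
    "participant_slopes",
    "condition_keys",
]

logger = logging.getLogger(__name__)

CONDITION_KEYS = ["clamp_mag", "jump_rel", "jump_event", "feedback_present"]


class AnalysisError(ValueError):
    """The analysis cannot proceed on the given data."""


def condition_keys() -> list[str]:
    """Column names identifying a normalized condition."""
    return list(CONDITION_KEYS)


# ---------------------------------------------------------------------------
# outlier exclusion
# ---------------------------------------------------------------------------


def flag_outliers(trials: pd.DataFrame, window: int = 5, z: float = 3.0) -> pd.DataFrame:
    """Flag hand angles deviating more than ``z`` SD from a moving window.

    The window is the ``window`` trials centered on the candidate trial,
    truncated at block edges; its mean and SD are computed *excluding* the
    candidate itself (otherwise a 5-trial window could never produce a
    3-SD deviation), with the SD floored at 1e-9.  A single pass over the
    raw series; no iterative re-flagging.  Blocks with fewer than 3 trials
    are left unflagged with a logged warning.

    Returns a copy with the ``excluded`` column set.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    out = trials.sort_values(["participant_id", "block_index", "trial_index"]).copy()
    excluded = np.zeros(len(out), dtype=bool)
    half = window // 2
    pos = 0
    for (pid, block), g in out.groupby(["participant_id", "block_index"], sort=False):
        h = g["hand_angle_deg"].to_numpy()
        n = len(h)
        if n < 3:
            logger.warning(
                "participant %s block %s has %d < 3 trials; outlier filter skipped",
                pid, block, n,
            )
            pos += n
            continue
        s = pd.Series(h)
        roll = s.rolling(window, center=True, min_periods=1)
        cnt = roll.count().to_numpy()
        tot = roll.sum().to_numpy()
        tot2 = pd.Series(h**2).rolling(window, center=True, min_periods=1).sum().to_numpy()
        m = cnt - 1  # leave-one-out sample size
        loo_mean = (tot - h) / m
        loo_var = np.maximum(tot2 - h**2 - m * loo_mean**2, 0.0) / np.maximum(m - 1, 1)
        loo_sd = np.maximum(np.sqrt(loo_var), 1e-9)
        excluded[pos : pos + n] = np.abs(h - loo_mean) > z * loo_sd
        pos += n
    out["excluded"] = excluded
    return out


# ---------------------------------------------------------------------------
# trial-pair deltas
# ---------------------------------------------------------------------------


def compute_deltas(trials: pd.DataFrame) -> pd.DataFrame:
    """Change in hand angle for each adjacent non-excluded trial pair.

    For every pair (n, n+1) of consecutive trials in the same block with
    neither trial excluded, emit ``delta_raw = hand[n+1] - hand[n]``
    attributed to trial n's raw condition.  Pairs spanning an excluded
    trial, a gap in trial indices, or a block boundary are dropped.
    """
    t = trials.sort_values(["participant_id", "block_index", "trial_index"])
    nxt = t.groupby(["participant_id", "block_index"], sort=False).shift(-1)
    nxt_excluded = nxt["excluded"].astype("boolean").fillna(True).astype(bool)
    ok = (
        (nxt["trial_index"] == t["trial_index"] + 1)
        & ~t["excluded"].astype(bool)
        & ~nxt_excluded
    )
    out = t.loc[ok, [
        "participant_id", "trial_index", "block_index",
        "clamp_deg", "jump_deg", "jump_event", "feedback_type",
    ]].copy()
    out = out.rename(columns={"trial_index": "source_trial_index"})
    out["delta_raw"] = (nxt["hand_angle_deg"] - t["hand_angle_deg"])[ok]
    return out.reset_index(drop=True)


def normalize_signs(deltas: pd.DataFrame) -> pd.DataFrame:
    """Map raw signed deltas into the normalized frame.

    Adds ``clamp_mag``, ``jump_rel``, ``jump_event`` (event flag preserved),
    ``feedback_present`` and ``delta`` columns; applying it to records whose
    clamps are already non-negative is the identity on the delta values.
    """
    out = deltas.copy()
    conds = [
        normalize_condition(c, j, bool(e), fb)
        for c, j, e, fb in zip(
            out["clamp_deg"], out["jump_deg"], out["jump_event"], out["feedback_type"]
        )
    ]
    out["clamp_mag"] = [c.clamp_mag for c, _ in conds]
    out["jump_rel"] = [c.jump_rel for c, _ in conds]
    out["jump_event"] = [c.jump_event for c, _ in conds]
    out["feedback_present"] = [c.feedback_present for c, _ in conds]
    out["delta"] = out["delta_raw"].to_numpy() * np.array([s for _, s in conds])
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def condition_medians(
    norm_deltas: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant condition medians and their group summary.

    Returns ``(per_participant, group_means)``: the first has one row per
    participant x condition with the median normalized delta; the second
    aggregates across participants (mean, SEM = sd/sqrt(n), n).  Conditions
    a participant never saw are simply absent, never zero-filled.
    """
    per = (
        norm_deltas.groupby(["participant_id"] + CONDITION_KEYS, sort=True)["delta"]
        .median()
        .reset_index()
        .rename(columns={"delta": "median_delta"})
    )
    g = per.groupby(CONDITION_KEYS, sort=True)["median_delta"]
    group = g.agg(mean="mean", sd="std", n="count").reset_index()
    group["sem"] = group["sd"] / np.sqrt(group["n"])
    group.loc[group["n"] == 1, "sem"] = np.nan
    return per, group.drop(columns="sd")


def _design_matrix(g: pd.DataFrame, design: str) -> tuple[np.ndarray, list[str]]:
    clamp = g["clamp_deg"].to_numpy(float)
    jump = g["jump_deg"].to_numpy(float)
    # TE-only perturbation size, sign-flipped so that a learning effect
    # yields a negative slope for both trial types
    x_jump = np.where(clamp == 0, -jump, 0.0)
    if design == "by_type":
        cols = [np.ones(len(g)), clamp, x_jump]
        names = ["intercept", "clamp_slope", "jump_slope"]
    elif design == "main_effects":
        is_te = (clamp == 0) & ((jump != 0) | g["jump_event"].astype(bool)
                                | (g["feedback_type"] == "none"))
        cols = [np.ones(len(g)), clamp + x_jump, is_te.astype(float)]
        names = ["intercept", "size_slope", "type_te"]
    else:
        raise ValueError(f"unknown design {design!r}")
    return np.column_stack(cols), names


@dataclass
class SlopeSummary:
    """Group-level summary of per-participant regression coefficients."""

    per_participant: pd.DataFrame
    summary: pd.DataFrame  # coef, mean, sem, t, p, df, n


def participant_slopes(deltas: pd.DataFrame, design: str = "by_type") -> SlopeSummary:
    """Per-participant OLS of raw deltas on signed perturbation size.

    ``design="by_type"`` fits intercept + a clamp-size slope + a (sign-
    flipped) jump-size slope; ``design="main_effects"`` fits a common size
    slope plus a perturbation-type offset.  Requires at least two distinct
    sizes per fitted column; a rank-deficient design raises
    :class:`AnalysisError` naming the collinear columns.  Group inference
    is a one-sample t-test of each coefficient's participant mean against 0.
    """
    rows = []
    for pid, g in deltas.groupby("participant_id", sort=True):
        X, names = _design_matrix(g, design)
        keep = [i for i in range(X.shape[1]) if i == 0 or np.ptp(X[:, i]) > 0]
        if np.linalg.matrix_rank(X[:, keep]) < len(keep):
            bad = [names[i] for i in keep if i > 0]
            raise AnalysisError(
                f"rank-deficient regression design for participant {pid}; "
                f"collinear columns among {bad}"
            )
        fit = sm.OLS(g["delta_raw"].to_numpy(), X[:, keep]).fit()
        coefs = dict.fromkeys(names, np.nan)
        for i, c in zip(keep, fit.params):
            coefs[names[i]] = c
        rows.append({"participant_id": pid, **coefs})
    per = pd.DataFrame(rows)
    stats_rows = []
    for name in per.columns[1:]:
        vals = per[name].dropna().to_numpy()
        n = len(vals)
        mean = vals.mean() if n else np.nan
        sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        if n > 1 and vals.std(ddof=1) > 0:
            t, p = stats.ttest_1samp(vals, 0.0)
        else:
            t, p = (0.0, 1.0) if n and mean == 0 else (np.nan, np.nan)
        stats_rows.append(
            {"coef": name, "mean": mean, "sem": sem, "t": t, "p": p,
             "df": n - 1, "n": n}
        )
    return SlopeSummary(per_participant=per, summary=pd.DataFrame(stats_rows))
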