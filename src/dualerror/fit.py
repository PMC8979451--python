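"""Model fitting, comparison, bootstrapping and derived quantities.

The six candidate models are fit to group-averaged condition means by
bounded multi-start least squares (both clamp magnitudes jointly), ranked
by R^2 and AIC, and parameter confidence intervals are obtained by
resampling participants with replacement within each clamp group.

Conventions
-----------
- The baseline update map ``u0`` is *fixed* from the empirical no-jump
  condition means of the dataset being fitted (per the ``u0_composition``
  switch of :func:`dualerror.models.effective_u0`), so only the
  attentional / reward / TE parameters are free -- 0 to 3 per model.
- ``R^2 = 1 - SSE/SST`` with SST taken against the grand mean of the
  fitted data points; a model worse than the grand mean scores negative.
- ``AIC = n * ln(SSE/n) + 2k`` with ``n`` the number of fitted condition
  means (Gaussian residuals, additive constants dropped; negative at small
  SSE).  Only orderings and AIC differences are meaningful.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import analyze
from .models import (
    DEFAULT_BOUNDS,
    ConfigurationError,
    ModelParams,
    ModelSpec,
    NormalizedCondition,
    all_specs,
    effective_u0,
    predict_total_update,
)

__all__ = [
    "FitResult",
    "ModelComparison",
    "BootstrapResult",
    "fit_model",
    "fit_all_models",
    "compare_models",
    "bootstrap_ci",
    "derived_quantities",
    "brute_force_fit",
    "means_from_trials",
]

logger = logging.getLogger(__name__)

_SSE_FLOOR = 1e-12


@dataclass
class FitResult:
    """One model's least-squares fit to a set of condition means."""

    spec: ModelSpec
    params: ModelParams
    free_values: dict[str, float]
    sse: float
    r2: float
    aic: float
    k: int
    n_points: int
    n_starts: int
    best_start_index: int
    converged: bool
    composition: str
    no_jump_means: dict[float, float]

    @property
    def model_id(self) -> str:
        return self.spec.model_id


def _conditions_from_means(condition_means: pd.DataFrame) -> list[NormalizedCondition]:
    conds = []
    for row in condition_means.itertuples(index=False):
        conds.append(
            NormalizedCondition(
                clamp_mag=float(row.clamp_mag),
                jump_rel=float(row.jump_rel),
                jump_event=bool(row.jump_event),
                feedback_present=bool(getattr(row, "feedback_present", True)),
            )
        )
    return conds


def _no_jump_means(condition_means: pd.DataFrame) -> dict[float, float]:
    mask = (
        (condition_means["jump_rel"] == 0)
        & (~condition_means["jump_event"].astype(bool))
        & condition_means.get("feedback_present", True)
    )
    rows = condition_means[mask]
    return {float(c): float(m) for c, m in zip(rows["clamp_mag"], rows["mean"])}


def _check_u0_coverage(
    u0: Mapping[float, float], conds: Sequence[NormalizedCondition]
) -> None:
    missing = sorted({c.clamp_mag for c in conds} - set(u0))
    if missing:
        raise ConfigurationError(
            f"no empirical no-jump mean available for clamp magnitude(s) "
            f"{missing}; cannot fix u0"
        )


def _objective_factory(spec, conds, y, w, base_params, no_jump, composition):
    names = spec.free_params

    def residuals(theta: np.ndarray) -> np.ndarray:
        params = base_params
        for name, val in zip(names, theta):
            params = _with(params, name, float(val))
        u0 = effective_u0(spec, params, no_jump, composition)
        params = params.with_u0(u0)
        pred = np.array([predict_total_update(spec, params, c) for c in conds])
        return (pred - y) * w

    return residuals


def _with(params: ModelParams, name: str, value: float) -> ModelParams:
    from dataclasses import replace

    return replace(params, **{name: value})


def fit_model(
    spec: ModelSpec,
    condition_means: pd.DataFrame,
    u0_fixed: Optional[Mapping[float, float]] = None,
    n_starts: int = 10,
    seed: int = 0,
    composition: str = "constrained",
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
    weighting: Optional[str] = None,
) -> FitResult:
    """Fit one model to condition means by bounded multi-start least squares.

    ``condition_means`` needs columns ``clamp_mag, jump_rel, jump_event,
    mean`` (optionally ``feedback_present`` and ``sem``).  ``u0_fixed``
    overrides the empirical no-jump means used to fix the baseline map;
    by default they are read off the data itself.  Starts are drawn
    uniformly within the parameter bounds from a seeded generator; ties
    break toward the lowest SSE, then the lowest start index.
    ``weighting="inv_sem"`` scales residuals by ``1/sem``.
    """
    conds = _conditions_from_means(condition_means)
    if not conds:
        raise ValueError("condition_means is empty")
    y = condition_means["mean"].to_numpy(float)
    if weighting is None:
        w = np.ones_like(y)
    elif weighting == "inv_sem":
        sem = condition_means["sem"].to_numpy(float)
        if not np.all(np.isfinite(sem)) or np.any(sem <= 0):
            raise ValueError("inv_sem weighting requires finite positive sem values")
        w = 1.0 / sem
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    no_jump = dict(u0_fixed) if u0_fixed is not None else _no_jump_means(condition_means)
    _check_u0_coverage(no_jump, conds)

    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    names = spec.free_params
    base = ModelParams(u0={})
    residuals = _objective_factory(spec, conds, y, w, base, no_jump, composition)

    if not names:  # fully fixed model: nothing to optimize
        sse = float(np.sum(residuals(np.empty(0)) ** 2))
        best_theta, best_sse, best_start, converged = np.empty(0), sse, 0, True
    else:
        lo = np.array([box[n][0] for n in names])
        hi = np.array([box[n][1] for n in names])
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF17]))
        starts = rng.uniform(lo, hi, size=(n_starts, len(names)))
        best_theta, best_sse, best_start, converged = None, np.inf, -1, False
        for i, x0 in enumerate(starts):
            try:
                res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
            except Exception:  # singular steps etc.; count as failed start
                logger.debug("start %d failed for %s", i, spec.model_id, exc_info=True)
                continue
            sse_i = float(2 * res.cost)
            if res.success and sse_i < best_sse - 1e-15:
                best_theta, best_sse, best_start = res.x, sse_i, i
                converged = True
        if best_theta is None:
            logger.warning("no start converged for model %s", spec.model_id)
            best_theta, best_sse, best_start = starts[0], float(
                np.sum(residuals(starts[0]) ** 2)
            ), 0

    params = base
    for name, val in zip(names, best_theta):
        params = _with(params, name, float(val))
    params = params.with_u0(effective_u0(spec, params, no_jump, composition))

    n = len(y)
    sst = float(np.sum(((y - y.mean()) * w) ** 2))
    r2 = 1.0 - best_sse / sst if sst > 0 else (1.0 if best_sse < _SSE_FLOOR else -np.inf)
    aic = n * math.log(max(best_sse, _SSE_FLOOR) / n) + 2 * spec.k
    return FitResult(
        spec=spec,
        params=params,
        free_values={n_: getattr(params, n_) for n_ in names},
        sse=best_sse,
        r2=r2,
        aic=aic,
        k=spec.k,
        n_points=n,
        n_starts=n_starts if names else 1,
        best_start_index=best_start,
        converged=converged,
        composition=composition,
        no_jump_means=dict(no_jump),
    )


def fit_all_models(
    condition_means: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    composition: str = "constrained",
    **kwargs,
) -> dict[str, FitResult]:
    """Fit all six candidate models to the same condition means."""
    seeds = np.random.SeedSequence([int(seed), 0xA11]).generate_state(6) % (2**31)
    return {
        spec.model_id: fit_model(
            spec, condition_means, n_starts=n_starts, seed=int(s),
            composition=composition, **kwargs,
        )
        for spec, s in zip(all_specs(), seeds)
    }


@dataclass
class ModelComparison:
    """AIC ranking of fits to one dataset."""

    table: pd.DataFrame  # model_id, k, sse, r2, aic, delta_aic, rank
    aic_r2_agree: bool

    @property
    def best_model_id(self) -> str:
        return str(self.table.iloc[0]["model_id"])


def compare_models(fits: Sequence[FitResult]) -> ModelComparison:
    """Rank fits by AIC (ascending); flags AIC/R^2 disagreement."""
    if not fits:
        raise ValueError("no fits to compare")
    n_points = {f.n_points for f in fits}
    if len(n_points) > 1:
        raise ValueError(
            f"fits are not comparable: mixed n_points {sorted(n_points)}"
        )
    rows = [
        {"model_id": f.model_id, "k": f.k, "sse": f.sse, "r2": f.r2,
         "aic": f.aic, "converged": f.converged}
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values(
        ["aic", "k", "model_id"], kind="mergesort"
    ).reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    table["rank"] = np.arange(1, len(table) + 1)
    agree = table.iloc[0]["r2"] == table["r2"].max()
    return ModelComparison(table=table, aic_r2_agree=bool(agree))


@dataclass
class BootstrapResult:
    """Participant-level bootstrap of a model's parameter estimates."""

    B: int
    samples: pd.DataFrame          # one row per successful resample
    ci: dict[str, tuple[float, float]]
    mean: dict[str, float]
    sd: dict[str, float]
    n_failed: int = 0


def means_from_trials(
    trials: pd.DataFrame, already_flagged: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the model-free pipeline: outliers -> deltas -> normalization ->
    medians.  Returns (per-participant medians, group condition means)."""
    t = trials if already_flagged else analyze.flag_outliers(trials)
    deltas = analyze.normalize_signs(analyze.compute_deltas(t))
    return analyze.condition_medians(deltas)


def _participant_groups(trials: pd.DataFrame) -> pd.Series:
    """Group label per participant: the set of nonzero clamp magnitudes
    they experienced (e.g. the +/-3 vs +/-7 deg clamp groups)."""
    mags = trials.assign(mag=trials["clamp_deg"].abs())
    return (
        mags[mags["mag"] > 0]
        .groupby("participant_id")["mag"]
        .agg(lambda v: tuple(sorted(set(v))))
        .reindex(trials["participant_id"].unique(), fill_value=())
    )


def bootstrap_ci(
    trials: pd.DataFrame,
    spec: ModelSpec,
    B: int = 1000,
    seed: int = 0,
    n_starts: int = 10,
    composition: str = "constrained",
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
) -> BootstrapResult:
    """Percentile bootstrap CIs by resampling participants within groups.

    For each of ``B`` resamples, participants are drawn with replacement
    within their clamp group, group-averaged condition means are rebuilt
    from the resampled participants' condition medians (the fixed ``u0``
    is re-derived from each resample's own no-jump means), and the model
    is refit.  Resamples lacking any condition present in the full data
    are dropped and counted in ``n_failed``.
    """
    per, full_means = means_from_trials(trials)
    full_conditions = set(map(tuple, full_means[analyze.condition_keys()].to_numpy()))
    groups = _participant_groups(trials)
    by_group: dict[tuple, np.ndarray] = {
        g: ids.index.to_numpy() for g, ids in groups.groupby(groups)
    }
    per_indexed = per.set_index("participant_id")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB007]))
    refit_seeds = rng.integers(0, 2**31 - 1, size=B)
    rows, n_failed = [], 0
    for b in range(B):
        sampled = []
        for g, ids in by_group.items():
            take = rng.choice(ids, size=len(ids), replace=True)
            sampled.extend(take)
        boot = per_indexed.loc[sampled].reset_index(drop=True)
        means_b = (
            boot.groupby(analyze.condition_keys(), sort=True)["median_delta"]
            .mean()
            .reset_index()
            .rename(columns={"median_delta": "mean"})
        )
        got = set(map(tuple, means_b[analyze.condition_keys()].to_numpy()))
        if got != full_conditions:
            n_failed += 1
            continue
        try:
            fit = fit_model(
                spec, means_b, n_starts=n_starts, seed=int(refit_seeds[b]),
                composition=composition, bounds=bounds,
            )
        except Exception:
            logger.warning("bootstrap refit %d failed", b, exc_info=True)
            n_failed += 1
            continue
        rows.append({"resample": b, "sse": fit.sse, **fit.free_values})
    if n_failed:
        logger.info("bootstrap: %d of %d resamples dropped", n_failed, B)
    samples = pd.DataFrame(rows)
    param_cols = list(spec.free_params)
    ci, mean, sd = {}, {}, {}
    for name in param_cols:
        v = samples[name].to_numpy() if len(samples) else np.array([np.nan])
        ci[name] = (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        mean[name] = float(np.mean(v))
        sd[name] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return BootstrapResult(
        B=B, samples=samples, ci=ci, mean=mean, sd=sd, n_failed=n_failed
    )


def derived_quantities(
    fit: Union[FitResult, ModelParams],
    no_jump_means: Mapping[float, float],
) -> dict:
    """Interpretable quantities implied by a (distracted SPE+TE) fit.

    Returns, per clamp magnitude, the percentage of the observed no-jump
    update attributable to the TE process
    (``100 * beta_te * theta_c / no_jump_mean``), plus the fixed
    attentional cost as a percentage (``100 * (1 - c_j)``) and the jump
    size beyond which SPE-driven learning is effectively abolished
    (``3 * sigma_d``, the 3-sigma point of the attentional decay).
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    te_fraction = {}
    for clamp_mag, mean in no_jump_means.items():
        if clamp_mag == 0:
            continue
        if mean == 0:
            raise ValueError(
                f"TE fraction undefined: no-jump mean is 0 at clamp {clamp_mag}deg"
            )
        te_fraction[float(clamp_mag)] = 100.0 * params.beta_te * clamp_mag / mean
    return {
        "te_fraction_pct": te_fraction,
        "fixed_cost_pct": 100.0 * (1.0 - params.c_j),
        "effective_jump_range_deg": 3.0 * params.sigma_d,
    }


def brute_force_fit(
    spec: ModelSpec,
    condition_means: pd.DataFrame,
    n_grid: int = 21,
    composition: str = "constrained",
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
    u0_fixed: Optional[Mapping[float, float]] = None,
) -> tuple[dict[str, float], float, dict[str, float]]:
    """Exhaustive lattice search over the parameter box.

    Independent oracle for the optimizer: evaluates the SSE on a regular
    ``n_grid``-per-axis lattice and returns ``(best_params, best_sse,
    cell_widths)``.  The optimizer's minimum should be at least as good
    and lie within one grid cell of the lattice minimum.
    """
    conds = _conditions_from_means(condition_means)
    y = condition_means["mean"].to_numpy(float)
    no_jump = dict(u0_fixed) if u0_fixed is not None else _no_jump_means(condition_means)
    _check_u0_coverage(no_jump, conds)
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    names = spec.free_params
    residuals = _objective_factory(
        spec, conds, y, np.ones_like(y), ModelParams(u0={}), no_jump, composition
    )
    axes = [np.linspace(*box[n], n_grid) for n in names]
    cell = {n: (box[n][1] - box[n][0]) / (n_grid - 1) for n in names}
    best_sse, best = np.inf, ()
    for theta in itertools.product(*axes) if names else [()]:
        sse = float(np.sum(residuals(np.array(theta)) ** 2))
        if sse < best_sse:
            best_sse, best = sse, theta
    return dict(zip(names, best)), best_sse, cell
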