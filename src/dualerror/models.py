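"""Candidate models of implicit recalibration driven by two error signals.

In error-clamp reaching experiments the cursor travels at a fixed angle
(the clamp, ``theta_c``) relative to the original target, independent of the
hand, which isolates the sensory prediction error (SPE): the angle between
the cursor and the *original* target.  Displacing the target at movement
onset by ``theta_j`` (a target jump) independently manipulates the task
error (TE): the angle between the cursor and the *new* target.  The trial-n
perturbation produces a motor update observable as the change in hand angle
on trial n+1.

Six models describe how the two errors combine into a single update:

===================  =========================================================
family               SPE-driven update ``U_SPE``
===================  =========================================================
``invariant``        ``u0[theta_c]`` (target jumps are irrelevant)
``rewarded``         ``u0[theta_c] - gamma_r * exp(-(theta_c-theta_j)^2 /
                     (2*sigma_r^2))`` (attenuated by intrinsic reward when
                     the cursor lands in the jumped target)
``distracted``       ``u0[theta_c]`` on trials with a stationary, visible
                     target; ``c_j * u0[theta_c] * exp(-theta_j^2 /
                     (2*sigma_d^2))`` whenever the target is perturbed
                     (fixed attentional cost ``c_j`` plus a Gaussian decay
                     of width ``sigma_d`` with jump size)
===================  =========================================================

Each family comes in an SPE-only variant and an SPE+TE variant that adds a
linear TE process ``U_TE = beta_te * (theta_c - theta_j)``, which is zero
exactly when the target jumps onto the cursor.  The total update is
``U_total = U_SPE + U_TE``.

All predictions live in a sign-normalized frame: ``theta_c`` is the clamp
magnitude, ``theta_j`` is positive when the jump is toward/past the clamp
direction and negative when away, and positive updates point away from the
clamp.  :func:`normalize_condition` maps raw signed trials into this frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ConfigurationError",
    "ParameterDomainError",
    "NormalizedCondition",
    "ModelParams",
    "ModelSpec",
    "MODEL_IDS",
    "FAMILIES",
    "DEFAULT_BOUNDS",
    "normalize_condition",
    "predict_spe_update",
    "predict_te_update",
    "predict_total_update",
    "predict_condition_curve",
]


class ConfigurationError(KeyError):
    """A model was asked about a condition it is not configured for."""


class ParameterDomainError(ValueError):
    """A parameter lies outside the domain the owning model requires."""


FAMILIES = ("invariant", "rewarded", "distracted")

#: Fitting boxes, generous around plausible values.  Widths in degrees.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "gamma_r": (0.0, 5.0),
    "sigma_r": (1e-3, 30.0),
    "c_j": (1e-3, 1.5),
    "sigma_d": (1e-3, 90.0),
    "beta_te": (-0.5, 0.5),
}


@dataclass(frozen=True)
class NormalizedCondition:
    """A sign-normalized perturbation condition.

    Parameters
    ----------
    clamp_mag
        Clamp magnitude ``theta_c`` in degrees, >= 0.
    jump_rel
        Signed target jump ``theta_j`` in degrees relative to the clamp
        direction: positive = toward/past the clamp, negative = away.
    jump_event
        True for any target perturbation, including a jump-in-place
        flicker (``jump_rel == 0`` with ``jump_event=True``).
    feedback_present
        False on no-cursor trials (TE-only without visual feedback).
    """

    clamp_mag: float
    jump_rel: float
    jump_event: bool = False
    feedback_present: bool = True

    def __post_init__(self) -> None:
        if self.clamp_mag < 0:
            raise ValueError(f"clamp_mag must be >= 0, got {self.clamp_mag}")
        if self.jump_rel != 0 and not self.jump_event:
            raise ValueError(
                "a nonzero jump_rel implies jump_event=True "
                f"(got jump_rel={self.jump_rel}, jump_event=False)"
            )


def normalize_condition(
    clamp_deg: float,
    jump_deg: float,
    jump_event: bool,
    feedback_type: str = "clamp",
) -> tuple[NormalizedCondition, float]:
    """Map a raw signed trial into the normalized frame.

    Returns ``(condition, sign)`` where ``sign`` converts a raw hand-angle
    change into the normalized one (``delta = delta_raw * sign``) and,
    symmetrically, a normalized model update back into raw coordinates.

    Conventions: for a nonzero clamp, ``theta_c = |clamp|``,
    ``theta_j = jump * sign(clamp)`` and positive deltas point away from
    the clamp (``sign = -sign(clamp)``).  For TE-only trials (zero clamp,
    nonzero jump) ``theta_j = |jump|`` and positive deltas follow the jump
    (``sign = sign(jump)``).  The null condition is left untouched.
    """
    feedback_present = feedback_type != "none"
    jump_event = bool(jump_event) or jump_deg != 0
    if clamp_deg != 0:
        s = -math.copysign(1.0, clamp_deg)
        cond = NormalizedCondition(
            clamp_mag=abs(clamp_deg),
            jump_rel=jump_deg * math.copysign(1.0, clamp_deg),
            jump_event=jump_event,
            feedback_present=feedback_present,
        )
    elif jump_deg != 0:
        s = math.copysign(1.0, jump_deg)
        cond = NormalizedCondition(
            clamp_mag=0.0,
            jump_rel=abs(jump_deg),
            jump_event=True,
            feedback_present=feedback_present,
        )
    else:
        s = 1.0
        cond = NormalizedCondition(
            clamp_mag=0.0,
            jump_rel=0.0,
            jump_event=jump_event,
            feedback_present=feedback_present,
        )
    return cond, s


def _round_key(clamp_mag: float) -> float:
    return round(float(clamp_mag), 6)


@dataclass
class ModelParams:
    """Parameter set shared by all six models.

    ``u0`` maps each clamp magnitude to its baseline SPE-driven update (the
    no-jump update, in degrees); during fitting it is fixed from empirical
    no-jump means rather than estimated.  The remaining fields are the free
    parameters of the richer families; unused ones are ignored.
    """

    u0: Mapping[float, float] = field(default_factory=dict)
    gamma_r: float = 0.0  # reward attenuation gain, degrees
    sigma_r: float = 1.0  # reward attenuation width, degrees
    c_j: float = 1.0      # fixed attentional cost multiplier, in (0, 1.5]
    sigma_d: float = 1.0  # attentional Gaussian-decay width, degrees
    beta_te: float = 0.0  # TE learning-rate slope, dimensionless

    def __post_init__(self) -> None:
        self.u0 = {_round_key(k): float(v) for k, v in dict(self.u0).items()}

    def u0_at(self, clamp_mag: float) -> float:
        key = _round_key(clamp_mag)
        try:
            return self.u0[key]
        except KeyError:
            raise ConfigurationError(
                f"no baseline update u0 configured for clamp magnitude "
                f"{clamp_mag}deg (available: {sorted(self.u0)})"
            ) from None

    def with_u0(self, u0: Mapping[float, float]) -> "ModelParams":
        return replace(self, u0=dict(u0))


@dataclass(frozen=True)
class ModelSpec:
    """Identifies one of the six candidate models."""

    family: str
    include_te: bool

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; expected one of {FAMILIES}"
            )

    @property
    def model_id(self) -> str:
        return f"{self.family}_spe" + ("_te" if self.include_te else "")

    @property
    def free_params(self) -> tuple[str, ...]:
        names: tuple[str, ...] = ()
        if self.family == "rewarded":
            names = ("gamma_r", "sigma_r")
        elif self.family == "distracted":
            names = ("c_j", "sigma_d")
        if self.include_te:
            names = names + ("beta_te",)
        return names

    @property
    def k(self) -> int:
        return len(self.free_params)

    @classmethod
    def from_id(cls, model_id: str) -> "ModelSpec":
        for spec in all_specs():
            if spec.model_id == model_id:
                return spec
        raise ValueError(
            f"unknown model id {model_id!r}; expected one of {MODEL_IDS}"
        )


def all_specs() -> list[ModelSpec]:
    """The six candidate models, SPE-only first within each family."""
    return [
        ModelSpec(family, include_te)
        for family in FAMILIES
        for include_te in (False, True)
    ]


MODEL_IDS = tuple(spec.model_id for spec in all_specs())


def predict_spe_update(
    spec: ModelSpec, params: ModelParams, cond: NormalizedCondition
) -> float:
    """SPE-driven component of the update, in degrees (normalized frame).

    Zero when no cursor feedback is shown (no SPE exists).
    """
    if not cond.feedback_present:
        return 0.0
    base = params.u0_at(cond.clamp_mag)
    if spec.family == "invariant":
        return base
    if spec.family == "rewarded":
        if params.sigma_r <= 0:
            raise ParameterDomainError(
                f"sigma_r must be > 0 for the rewarded family, got {params.sigma_r}"
            )
        gap = cond.clamp_mag - cond.jump_rel
        return base - params.gamma_r * math.exp(-(gap**2) / (2.0 * params.sigma_r**2))
    # distracted: attentional costs apply only when the target was perturbed
    if not cond.jump_event:
        return base
    if params.sigma_d <= 0:
        raise ParameterDomainError(
            f"sigma_d must be > 0 for the distracted family, got {params.sigma_d}"
        )
    return (
        params.c_j
        * base
        * math.exp(-(cond.jump_rel**2) / (2.0 * params.sigma_d**2))
    )


def predict_te_update(params: ModelParams, cond: NormalizedCondition) -> float:
    """TE-driven component ``beta_te * (theta_c - theta_j)`` in degrees.

    Vanishes exactly when the target jumps onto the cursor
    (``theta_j == theta_c``), i.e. when TE is nullified.
    """
    return params.beta_te * (cond.clamp_mag - cond.jump_rel)


def predict_total_update(
    spec: ModelSpec, params: ModelParams, cond: NormalizedCondition
) -> float:
    """Total predicted update ``U_SPE (+ U_TE)`` in degrees."""
    total = predict_spe_update(spec, params, cond)
    if spec.include_te:
        total += predict_te_update(params, cond)
    return total


def predict_condition_curve(
    spec: ModelSpec,
    params: ModelParams,
    clamp_mag: float,
    jump_grid: Iterable[float],
    jump_event_at_zero: bool = False,
) -> list[tuple[float, float]]:
    """Predicted update across a grid of relative jump sizes.

    Nonzero grid entries are jump trials; a zero entry is a no-jump trial
    unless ``jump_event_at_zero`` is set, which makes it the jump-in-place
    (flicker) condition instead.
    """
    out = []
    for j in jump_grid:
        cond = NormalizedCondition(
            clamp_mag=clamp_mag,
            jump_rel=float(j),
            jump_event=(j != 0) or jump_event_at_zero,
        )
        out.append((float(j), predict_total_update(spec, params, cond)))
    return out


def effective_u0(
    spec: ModelSpec,
    params: ModelParams,
    no_jump_means: Mapping[float, float],
    composition: str = "constrained",
) -> dict[float, float]:
    """Baseline-update map implied by empirical no-jump condition means.

    ``composition`` selects how the fixed baseline combines with the other
    processes at the no-jump condition:

    - ``"literal"``: ``u0`` *is* the empirical no-jump mean; for SPE+TE
      models the predicted no-jump total then exceeds the empirical mean by
      ``beta_te * theta_c``.
    - ``"constrained"`` (default): ``u0`` is back-solved so the model's
      predicted no-jump total equals the empirical mean exactly.  This is
      the self-consistent reading: the derived TE fraction
      ``beta_te * theta_c / no_jump_mean`` then partitions the observed
      no-jump update, matching how the no-jump change decomposes into SPE
      and TE shares.

    ``u0`` enters every family's no-jump prediction additively with unit
    coefficient, so the constrained solution is exact and closed-form.
    """
    if composition not in ("literal", "constrained"):
        raise ValueError(
            f"composition must be 'literal' or 'constrained', got {composition!r}"
        )
    means = {_round_key(k): float(v) for k, v in dict(no_jump_means).items()}
    if composition == "literal":
        return means
    zeroed = params.with_u0({k: 0.0 for k in means})
    out = {}
    for clamp_mag, m in means.items():
        cond = NormalizedCondition(clamp_mag=clamp_mag, jump_rel=0.0)
        offset = predict_total_update(spec, zeroed, cond)
        out[clamp_mag] = m - offset
    return out


def params_for_no_jump_totals(
    spec: ModelSpec,
    no_jump_totals: Mapping[float, float],
    **free: float,
) -> ModelParams:
    """Build parameters whose predicted no-jump totals match ``no_jump_totals``.

    Convenience for constructing generative ground truths: the free
    parameters are given by keyword and ``u0`` is solved so the model's
    no-jump predictions equal the requested totals.
    """
    params = ModelParams(u0={}, **free)
    u0 = effective_u0(spec, params, no_jump_totals, composition="constrained")
    return params.with_u0(u0)
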