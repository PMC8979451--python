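# Methods

This note documents the modeling conventions, generator assumptions and
numerical choices behind `dualerror`, in the spirit of a model
description section: what is assumed, what is configurable, and what
passing tests do and do not establish.

## The update models

Implicit recalibration is measured trial-by-trial: the perturbation on
trial *n* (a clamped cursor at angle θ_c relative to the target, possibly
combined with a target jump of θ_j) produces a change in hand angle on
trial *n + 1*, the motor update *U*. All model predictions live in a
**sign-normalized frame**: θ_c ≥ 0 is the clamp magnitude; θ_j > 0 means
the target jumped toward or past the clamped cursor and θ_j < 0 away
from it; positive updates point away from the clamp. Mirror-image raw
trials (clockwise/counterclockwise) collapse onto one condition. For
TE-only trials (zero clamp) the frame follows the jump instead: positive
updates point along the jump direction.

Six models combine an SPE-driven process with an optional TE-driven
process, U_total = U_SPE + U_TE:

- **Invariant SPE**: U_SPE = U₀(θ_c). Target jumps are irrelevant to
  SPE-driven learning.
- **Rewarded SPE**: U_SPE = U₀(θ_c) − γ_r · exp(−(θ_c − θ_j)²/2σ_r²).
  Learning is attenuated by an intrinsic reward signal peaking when the
  cursor lands in the (jumped) target; γ_r (deg) is the attenuation
  depth, σ_r (deg) its width. The attenuation is evaluated from the
  formula on every trial — no discrete hit/miss flag — and is negligible
  whenever |θ_c − θ_j| ≫ σ_r.
- **Distracted SPE**: U_SPE = U₀(θ_c) on trials with a stationary,
  continuously visible target; C_J · U₀(θ_c) · exp(−θ_j²/2σ_d²) on any
  trial with a target perturbation event, including a jump-in-place
  flicker (θ_j = 0 with an event). C_J ∈ (0, 1.5] is the fixed
  attentional cost of the perturbation event; σ_d (deg) the width of the
  Gaussian decay with jump size. Both Gaussian terms use negative
  exponents: the processes are decays, and a growing exponential would
  diverge and contradict the attenuation they describe.
- **TE process** (the `_te` variants): U_TE = β_TE · (θ_c − θ_j). The
  (θ_c − θ_j) form makes the TE contribution vanish exactly when the
  target jumps onto the cursor, grow when the target jumps away, and
  reverse when the target jumps past.

On no-feedback trials there is no cursor and hence no SPE; U_SPE is 0 by
construction and only the TE term (if any) survives. Setting β_TE = 0
collapses each SPE+TE model exactly onto its SPE-only counterpart, and
γ_r = 0 or {C_J = 1, σ_d → ∞} collapse the richer families onto the
invariant one; these nesting relations are enforced by property tests.

### Baseline composition (`u0_composition`)

U₀ is never a free parameter: it is fixed from the empirical no-jump
condition means of the dataset being fitted. Two readings of "fixed from
the data" are supported:

- `constrained` (default): U₀ is back-solved so that the model's
  *predicted total* at the no-jump condition equals the empirical mean.
  Under this reading the derived TE share, 100·β_TE·θ_c / mean,
  partitions the observed no-jump update into SPE and TE components
  (0.06°/0.5° = 12% at a 3° clamp with β_TE = 0.02), and simulation →
  fitting round trips are exactly self-consistent.
- `literal`: U₀ *is* the empirical no-jump mean. The SPE+TE prediction
  then overshoots the no-jump point by β_TE·θ_c, and refitting data
  generated under the same convention recovers a C_J biased low by
  roughly β_TE·θ_c/mean · C_J (≈ −0.1 here). The switch is retained
  because the composition convention is a genuine degree of freedom in
  this model class and making it explicit keeps the ambiguity testable.

Since U₀ enters every family's no-jump prediction additively with unit
coefficient, the constrained solution is closed-form.

## Experiment designs

Ten designs are reproduced with exact counts:

| id | trials | structure |
|---|---|---|
| exp1a | 804 | 4 alternating homogeneous mini-blocks × 201 (40 per signed type + 41 nulls); zero-mean every 20 trials |
| exp1b | 200 | mixed; 20/condition; clamp trials vs no-cursor jump trials |
| exp2a/b | 724 | fully interleaved; 80/combination, 84 at (0, 0); zero-mean every 24 trials |
| exp3a/b | 120 | 30 per sign-collapsed condition (toward / away / flicker / no-jump) at ±3° or ±7° clamps |
| exp4a–d | 252 | 18 per signed clamp × jump combination; jumps to ±30° |

Zero-mean windows are interpreted as consecutive *non-overlapping*
windows (every sliding window having zero mean would force a periodic
schedule). They are guaranteed constructively: trials are assembled from
mirror-image pairs plus zero-perturbation neutrals, dealt into windows
with an even neutral quota, and shuffled only within windows. Designs
without a stated window length satisfy a whole-block zero mean.

Two design-table readings worth recording: the ±0° jumps of the wide-
range sets are plain no-jump trials (the flicker manipulation belongs to
the two-clamp flicker design), and the 201-trial mini-block composition
(4 × 40 + 41) is taken as authoritative for exp1a, where an
across-experiment count of 84 null trials quoted elsewhere is
arithmetically incompatible (4 × 41 = 164); the validator reports actual
counts rather than enforcing the 84 there. The 84 figure *is* enforced
for exp2, where it is consistent.

## Synthetic cohorts

The generator stands in for raw data that are not publicly deposited.
Per participant, a latent reach-direction state x evolves as

    x₁ = 0,  hand_n = x_n + ε_n,  ε_n ~ N(0, noise_sd²),
    x_{n+1} = retention · x_n + s_n · U(cond_n),

with U the generative model's update in the normalized frame and s_n the
sign restoring raw coordinates. Defaults and what they emulate:

- `noise_sd = 0.15°`: execution noise sized so group-level condition
  SEMs at realistic trial counts land in the observed 0.1–0.2° range.
  Real motor noise is far larger (degrees); here the medians-of-many-
  trials pipeline is what matters, and this value reproduces the
  *aggregated* variability, not raw kinematic scatter.
- `retention = 1.0`: updates persist across the one-trial horizon the
  trial-pair statistic assumes. Values < 1 are available for robustness
  studies; the trial-pair statistic then under-recovers U by
  (1 − retention)·x_n terms.
- `between_subject_sd` (deg): participants share all free parameters and
  differ only by a multiplicative gain on U₀, parameterized as the
  spread in degrees of the largest-clamp baseline. Group fits average
  over participants, so only this mean structure matters downstream.
- Seeding: a master `SeedSequence` spawns one child stream per
  participant in order, so cohorts are bit-reproducible and participant
  streams are independent.

With `noise_sd = 0` and `retention = 1` the full simulate → analyze
round trip returns the generative update exactly for every condition,
model and design — the pipeline's core oracle. Passing it shows the
bookkeeping (pairing, sign conventions, aggregation) is exact; it says
nothing about robustness to model misspecification, kinematic artifacts,
online corrections or attentional lapses, none of which are simulated.

## Model-free pipeline

- **Outlier rule**: a trial is excluded when its hand angle deviates by
  more than 3 SD from the 5-trial window centered on it, with the
  window mean and SD computed *excluding the trial itself* (a 5-sample
  window including the candidate can never produce a 3-SD deviation:
  max deviation is (n−1)/√n ≈ 1.79 SD), SD floored at 1e-9, single
  pass, windows truncated at block edges. A consequence worth knowing:
  with only 4 reference samples, the flagging statistic on iid Gaussian
  data is t-distributed with 3 df, so the false-positive rate is
  P(|t₃| > 3/√1.25) ≈ 7.4% — far above the 2Φ(−3) ≈ 0.27% a
  normal-theory intuition suggests. The unit tests assert the
  t-distribution rate. On structured (smooth or slowly drifting) data
  the rate is much lower; the filter exists to catch isolated lapses,
  which it does exactly (verified against a brute-force reference).
- **Deltas**: hand_{n+1} − hand_n for consecutive same-block pairs with
  neither trial excluded, attributed to trial n's condition. Pairs
  spanning exclusions, index gaps or block boundaries are dropped
  (conditions change regime at boundaries).
- **Aggregation**: median per participant × condition (robust to
  residual lapses), then mean ± SEM across participants. Conditions a
  participant never saw are absent, not zero-filled.
- **Regressions**: per-participant OLS of raw deltas on signed clamp
  size and (sign-flipped) jump size — sign-flipped so that learning
  produces negative slopes for both trial types — with one-sample
  t-tests of the coefficient means against zero. Mixed-effects variants
  are out of scope; per-participant OLS + group t-tests is the
  implemented inference.

## Fitting and comparison

- Bounded least squares (`scipy.optimize.least_squares`, TRF) jointly
  over both clamp magnitudes; 10 uniform-in-bounds starts from a seeded
  generator; ties broken by lowest SSE then lowest start index.
  Bounds: γ_r ∈ [0, 5°], σ_r ∈ (0, 30°], C_J ∈ (0, 1.5],
  σ_d ∈ (0, 90°], β_TE ∈ [−0.5, 0.5] — generous boxes around plausible
  values, all configurable.
- R² = 1 − SSE/SST against the grand mean of the fitted points; a model
  worse than the grand mean scores negative (the invariant family on
  jump-modulated data typically lands near −0.5 to −0.9).
- AIC = n·ln(SSE/n) + 2k, n = number of condition means, no small-sample
  correction, constants dropped; SSE floored at 1e-12 inside the log so
  perfect fits stay finite while preserving exact ΔAIC = 2 for a useless
  extra parameter. Only orderings and ΔAIC are meaningful; absolute
  values depend on the dataset.
- Unweighted SSE by default; `weighting="inv_sem"` is available since
  weighting by precision is a defensible alternative the source analyses
  leave unspecified.
- Bootstrap: participants resampled with replacement within their clamp
  group; condition means rebuilt from the resample's per-participant
  medians; U₀ re-derived from the resample's own no-jump means; refit;
  percentile CIs. Resamples missing any condition are dropped and
  counted.
- An exhaustive lattice search (`brute_force_fit`) serves as an
  independent optimizer oracle. The one-grid-cell agreement check is
  meaningful only when the lattice can represent the optimum, so the
  oracle tests place the generative parameters on lattice nodes.

## Known limitations

- The generator's noise model is deliberately minimal (iid Gaussian on
  top of a deterministic state); it reproduces aggregate means and SEMs,
  not kinematics, reaction times or lapse structure.
- Absolute R²/AIC values from the original behavioral data are not
  reproducible without those data; only model orderings, parameter
  values and derived percentages are meaningful comparisons.
- TE-only learning is genuinely zero in the model family whenever
  feedback is absent only insofar as U_SPE = 0 there; SPE+TE generative
  models do predict small no-feedback TE responses (β_TE·θ_j), which is
  why null-result simulations use SPE-only ground truths.
- The schedule builder guarantees window balance exactly but does not
  emulate every pseudo-randomization detail of the original software
  (e.g. constraints on immediate repeats), which are unspecified.
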