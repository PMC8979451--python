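"""Perturbation-schedule generators for the ten experiment designs.

Each design pairs signed error-clamp angles with signed target jumps under
exact count and zero-mean constraints:

- ``exp1a`` (in-person): 804 perturbation trials in four alternating
  mini-blocks of 201, homogeneous in perturbation type (clamp-with-
  stationary-target vs. target-jump-with-0deg-clamp); the mean signed
  perturbation is zero in every consecutive 20-trial window.
- ``exp1b`` (online): 200 trials mixing clamp trials and no-cursor target
  jump trials, 20 per condition, zero-mean over the block.
- ``exp2a``/``exp2b`` (in-person): 724 fully interleaved trials, 80 per
  clamp x jump combination (84 for the 0,0 combination), zero-mean in every
  consecutive 24-trial window.
- ``exp3a``/``exp3b`` (online): 120 trials, 30 per sign-collapsed condition
  (jump-toward, jump-away, jump-in-place flicker, no-jump) at a +/-3 or
  +/-7 deg clamp.
- ``exp4a``..``exp4d`` (online): 252 trials, 18 per signed clamp x jump
  combination (2 clamps x 7 jumps), jumps out to +/-30 deg.

Zero-mean windows are guaranteed by construction: trials are assembled from
mirror-image pairs (a trial and its sign-flipped twin) plus zero-
perturbation "neutral" trials, dealt into fixed-length windows and shuffled
only within each window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXPERIMENT_IDS",
    "Schedule",
    "ScheduleReport",
    "ScheduleConstraintError",
    "generate_schedule",
    "validate_schedule",
    "expected_counts",
]

SCHEDULE_COLUMNS = [
    "trial",
    "block",
    "clamp_deg",
    "jump_deg",
    "jump_event",
    "feedback_type",
]


class ScheduleConstraintError(ValueError):
    """A design's counts cannot be arranged into zero-mean windows."""


@dataclass
class Schedule:
    """An ordered perturbation-trial list for one experiment."""

    experiment_id: str
    trials: pd.DataFrame
    rng_seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, experiment_id: str = "custom", rng_seed: int = -1):
        df = pd.read_csv(path)
        missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"schedule file missing required columns: {missing}")
        df["jump_event"] = df["jump_event"].astype(bool)
        return cls(experiment_id=experiment_id, trials=df, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# design tables
# ---------------------------------------------------------------------------

# a trial tuple: (clamp_deg, jump_deg, jump_event, feedback_type)
Combo = tuple[float, float, bool, str]


def _mirror(combo: Combo) -> Combo:
    clamp, jump, event, fb = combo
    return (-clamp, -jump, event, fb)


@dataclass(frozen=True)
class _BlockDesign:
    # mirror-symmetric combos: count applies to EACH member of the +/- pair
    pair_combos: tuple[tuple[Combo, int], ...]
    # zero-perturbation combos with their counts
    neutral_combos: tuple[tuple[Combo, int], ...]
    window: Optional[int]  # zero-mean window length; None = whole block


@dataclass(frozen=True)
class _Design:
    blocks: tuple[_BlockDesign, ...]
    total: int
    alternating: bool = False  # exp1a mini-block structure


def _clamp_block(clamps: Sequence[float], n: int, n_zero: int, window) -> _BlockDesign:
    pairs = tuple(((c, 0.0, False, "clamp"), n) for c in clamps)
    neutral = (((0.0, 0.0, False, "clamp"), n_zero),)
    return _BlockDesign(pairs, neutral, window)


def _jump_block(
    jumps: Sequence[float], n: int, n_zero: int, window, feedback: str
) -> _BlockDesign:
    pairs = tuple(((0.0, j, True, feedback), n) for j in jumps)
    neutral = (((0.0, 0.0, False, feedback), n_zero),)
    return _BlockDesign(pairs, neutral, window)


def _clamp_jump_block(
    clamp: float,
    rel_jumps: Sequence[float],
    n: int,
    flicker: int = 0,
    window=None,
) -> _BlockDesign:
    """Nonzero clamp paired with jumps given *relative* to the clamp sign."""
    pairs = []
    for rj in rel_jumps:
        if rj == 0:
            pairs.append(((clamp, 0.0, False, "clamp"), n))
        else:
            pairs.append(((clamp, rj * np.sign(clamp), True, "clamp"), n))
    if flicker:
        pairs.append(((clamp, 0.0, True, "clamp"), flicker))
    return _BlockDesign(tuple(pairs), (), window)


def _merge(*blocks: _BlockDesign) -> _BlockDesign:
    pairs = sum((b.pair_combos for b in blocks), ())
    neutral: dict[Combo, int] = {}
    for b in blocks:
        for combo, n in b.neutral_combos:
            neutral[combo] = neutral.get(combo, 0) + n
    window = blocks[0].window
    return _BlockDesign(pairs, tuple(neutral.items()), window)


def _designs() -> dict[str, _Design]:
    d: dict[str, _Design] = {}

    # Exp 1A: 4 alternating homogeneous mini-blocks of 201 (40 per signed
    # type + 41 nulls each), zero-mean every 20 trials.
    spe = _clamp_block([4.0, 16.0], 40, 41, window=20)
    te = _jump_block([4.0, 16.0], 40, 41, window=20, feedback="clamp")
    d["exp1a"] = _Design(blocks=(spe, te, spe, te), total=804, alternating=True)

    # Exp 1B: 200 mixed trials, 20 per condition; target-jump trials carry
    # no cursor feedback; zero-mean over the whole block.
    d["exp1b"] = _Design(
        blocks=(
            _merge(
                _clamp_block([4.0, 16.0], 20, 20, window=None),
                _jump_block([4.0, 16.0], 20, 20, window=None, feedback="none"),
            ),
        ),
        total=200,
    )

    # Exp 2: 724 mixed trials, 80 per combination, 84 at (0, 0), zero-mean
    # every 24 trials.  Set A jumps share the clamp's sign; Set B jumps go
    # either way.
    def exp2(rel_jumps_with_clamp, te_jumps):
        # clamp-trial jumps are given relative to a +4 clamp
        clamp_pairs = tuple(
            ((4.0, float(rj), rj != 0, "clamp"), 80) for rj in rel_jumps_with_clamp
        )
        te_pairs = tuple(((0.0, float(j), True, "clamp"), 80) for j in te_jumps)
        neutral = (((0.0, 0.0, False, "clamp"), 84),)
        return _Design(
            blocks=(_BlockDesign(clamp_pairs + te_pairs, neutral, window=24),),
            total=724,
        )

    d["exp2a"] = exp2([0.0, 4.0, 8.0], [4.0])
    d["exp2b"] = exp2([0.0, 8.0, -8.0], [8.0])

    # Exp 3: 120 trials, 30 per sign-collapsed condition (15 per clamp sign):
    # jump-toward, jump-away, jump-in-place, no-jump.
    def exp3(clamp):
        b = _clamp_jump_block(clamp, [3.0, -3.0, 0.0], 15, flicker=15, window=None)
        return _Design(blocks=(b,), total=120)

    d["exp3a"] = exp3(3.0)
    d["exp3b"] = exp3(7.0)

    # Exp 4: 252 trials, 18 per signed clamp x jump combination.
    def exp4(clamp, rel_jumps):
        b = _clamp_jump_block(clamp, rel_jumps, 18, window=None)
        return _Design(blocks=(b,), total=252)

    d["exp4a"] = exp4(3.0, [-10.0, -3.0, 0.0, 3.0, 7.0, 10.0, 17.0])
    d["exp4b"] = exp4(7.0, [-10.0, -3.0, 0.0, 3.0, 7.0, 10.0, 17.0])
    d["exp4c"] = exp4(3.0, [-30.0, -17.0, -10.0, 0.0, 10.0, 17.0, 30.0])
    d["exp4d"] = exp4(7.0, [-30.0, -17.0, -10.0, 0.0, 10.0, 17.0, 30.0])
    return d


_DESIGNS = _designs()
EXPERIMENT_IDS = tuple(sorted(_DESIGNS))


def expected_counts(experiment_id: str) -> dict[Combo, int]:
    """Per-combination trial counts the design prescribes (signed combos)."""
    design = _get_design(experiment_id)
    counts: dict[Combo, int] = {}
    for block in design.blocks:
        for combo, n in block.pair_combos:
            counts[combo] = counts.get(combo, 0) + n
            m = _mirror(combo)
            counts[m] = counts.get(m, 0) + n
        for combo, n in block.neutral_combos:
            counts[combo] = counts.get(combo, 0) + n
    return counts


def _get_design(experiment_id: str) -> _Design:
    try:
        return _DESIGNS[experiment_id]
    except KeyError:
        raise ValueError(
            f"unknown experiment id {experiment_id!r}; "
            f"supported: {list(EXPERIMENT_IDS)}"
        ) from None


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _build_block(block: _BlockDesign, rng: np.random.Generator) -> list[Combo]:
    """Arrange one block's trials into exact zero-mean windows.

    Pairs (a combo and its mirror) are indivisible units with zero summed
    perturbation; neutrals have zero perturbation individually.  Each
    window receives whole pairs plus an even quota of neutrals, then is
    shuffled internally, so every window mean is exactly zero.  Leftover
    trials beyond the last full window are drawn from the neutral pool.
    """
    pairs: list[tuple[Combo, Combo]] = []
    for combo, n in block.pair_combos:
        pairs.extend([(combo, _mirror(combo))] * n)
    neutrals: list[Combo] = []
    for combo, n in block.neutral_combos:
        neutrals.extend([combo] * n)

    n_total = 2 * len(pairs) + len(neutrals)
    window = block.window or n_total
    if window % 2 != 0 and window != n_total:
        raise ScheduleConstraintError(f"window length {window} must be even")
    n_windows = n_total // window
    leftover = n_total - n_windows * window
    if leftover > len(neutrals):
        raise ScheduleConstraintError(
            f"{leftover} leftover trials cannot be covered by "
            f"{len(neutrals)} zero-perturbation trials"
        )

    rng.shuffle(pairs)  # type: ignore[arg-type]
    rng.shuffle(neutrals)  # type: ignore[arg-type]
    tail = [neutrals.pop() for _ in range(leftover)]

    # distribute the remaining neutrals over windows in even-sized chunks
    # so each window splits into whole pairs + neutrals
    z = len(neutrals)
    if z % 2 != 0:
        raise ScheduleConstraintError(
            f"after the {leftover}-trial tail, {z} neutrals cannot be split "
            "evenly into zero-mean windows"
        )
    base = (z // n_windows) // 2 * 2 if n_windows else 0
    quota = [base] * n_windows
    extra = z - base * n_windows
    i = 0
    while extra > 0:
        quota[i % n_windows] += 2
        extra -= 2
        i += 1
    if any(q > window for q in quota):
        raise ScheduleConstraintError("more neutral trials than window slots")

    out: list[Combo] = []
    for q in quota:
        if (window - q) % 2 != 0:
            raise ScheduleConstraintError(
                f"window of {window} cannot hold {q} neutrals plus whole pairs"
            )
        take_pairs = (window - q) // 2
        if take_pairs > len(pairs):
            raise ScheduleConstraintError("not enough mirror pairs for window")
        chunk: list[Combo] = []
        for _ in range(take_pairs):
            a, b = pairs.pop()
            chunk.extend([a, b])
        for _ in range(q):
            chunk.append(neutrals.pop())
        perm = rng.permutation(len(chunk))
        out.extend([chunk[j] for j in perm])
    out.extend(tail)
    assert not pairs and not neutrals
    return out


def generate_schedule(
    experiment_id: str, seed: int, counterbalance_order: bool = False
) -> Schedule:
    """Generate a perturbation schedule for one experiment design.

    Deterministic for a fixed ``seed``.  ``counterbalance_order`` swaps
    which mini-block type comes first in the alternating ``exp1a`` design
    (no effect elsewhere).
    """
    design = _get_design(experiment_id)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C4ED]))
    blocks = list(design.blocks)
    if design.alternating and counterbalance_order:
        blocks = [blocks[1], blocks[0]] * (len(blocks) // 2)
    rows = []
    trial = 0
    for block_index, block in enumerate(blocks):
        for combo in _build_block(block, rng):
            clamp, jump, event, fb = combo
            rows.append((trial, block_index, clamp, jump, event, fb))
            trial += 1
    df = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    return Schedule(experiment_id=experiment_id, trials=df, rng_seed=seed)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ScheduleReport:
    """Outcome of checking a schedule against its design invariants."""

    experiment_id: str
    n_trials: int
    combo_counts: dict[Combo, int] = field(default_factory=dict)
    max_window_mean: float = 0.0
    block_homogeneous: bool = True
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _signed_error(row) -> float:
    # the perturbation a trial contributes to the zero-mean constraint:
    # the clamp on clamp trials, the jump on TE-only trials
    return row.clamp_deg if row.clamp_deg != 0 else row.jump_deg


def validate_schedule(
    schedule: Schedule, experiment_id: Optional[str] = None
) -> ScheduleReport:
    """Check counts, zero-mean windows and block structure; never raises
    on content problems -- every violated invariant is listed instead."""
    exp_id = experiment_id or schedule.experiment_id
    df = schedule.trials
    report = ScheduleReport(experiment_id=exp_id, n_trials=len(df))
    for row in df.itertuples(index=False):
        combo = (row.clamp_deg, row.jump_deg, bool(row.jump_event), row.feedback_type)
        report.combo_counts[combo] = report.combo_counts.get(combo, 0) + 1

    try:
        design = _get_design(exp_id)
    except ValueError:
        report.violations.append(f"unknown experiment id {exp_id!r}")
        return report

    expected = expected_counts(exp_id)
    for combo, n in expected.items():
        got = report.combo_counts.get(combo, 0)
        if got != n:
            report.violations.append(f"combo {combo}: expected {n} trials, got {got}")
    for combo in report.combo_counts:
        if combo not in expected:
            report.violations.append(f"unexpected combo {combo}")
    if len(df) != design.total:
        report.violations.append(
            f"total trials: expected {design.total}, got {len(df)}"
        )

    # zero-mean windows, block by block
    for (block_id,), g in df.groupby(["block"]):
        errs = np.array([_signed_error(r) for r in g.itertuples(index=False)])
        if len(errs) == 0:
            continue
        bdesign = design.blocks[block_id] if block_id < len(design.blocks) else None
        window = (bdesign.window if bdesign and bdesign.window else len(errs))
        n_windows = len(errs) // window
        for w in range(n_windows):
            m = errs[w * window : (w + 1) * window].mean()
            report.max_window_mean = max(report.max_window_mean, abs(m))
            if abs(m) > 1e-9:
                report.violations.append(
                    f"block {block_id}, window {w}: mean signed perturbation "
                    f"{m:+.3f}deg != 0"
                )
        total_mean = errs.mean()
        report.max_window_mean = max(report.max_window_mean, abs(total_mean))
        if abs(total_mean) > 1e-9:
            report.violations.append(
                f"block {block_id}: whole-block mean {total_mean:+.3f}deg != 0"
            )

    # exp1a mini-blocks must be homogeneous in perturbation type
    if design.alternating:
        for (block_id,), g in df.groupby(["block"]):
            types = {
                "jump" if c == 0 and (j != 0 or e) else "clamp"
                for c, j, e in zip(g.clamp_deg, g.jump_deg, g.jump_event)
                if c != 0 or j != 0 or e
            }
            if len(types) > 1:
                report.block_homogeneous = False
                report.violations.append(
                    f"block {block_id} mixes perturbation types {sorted(types)}"
                )
    return report
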