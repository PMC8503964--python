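"""Trial planning, headless session execution and trial-record CSV I/O.

Two protocols are supported.

* ``replication``: one condition per session.  Control sessions present 11
  reference contrasts (0.02-0.70, geometrically spaced) 10 times each in
  random order (110 trials); adaptation sessions present the upper 6 of
  those contrasts 10 times each (60 trials), preceded by 180 s of
  adaptation to a 0.7-contrast grating with 10 s top-ups between trials.
  The slider is the 1001-entry zero-prepended replication scale, unrotated.
* ``exercise``: one seamless session of 6 unrecorded practice trials, then
  60 control and 60 adaptation trials over the same 6 contrast levels, on
  the 1000-entry exercise scale which is freshly cut (rotated) at a uniform
  random position on every trial.

Sessions are headless: timing constants (adaptation duration, inter-trial
interval) are carried as metadata, never slept, and responses come from a
generative observer model rather than a human.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .observer import ADAPTATION, CONTROL, ObserverParams, expected_log_match, simulate_match
from .scale import (
    ContrastScale,
    build_exercise_scale,
    build_replication_scale,
    contrast_at,
    log_spaced,
    nearest_position,
    rotate,
)

__all__ = [
    "CONTROL_LEVELS",
    "ADAPTATION_LEVELS",
    "SessionConfig",
    "Trial",
    "TrialRecord",
    "replication_control_config",
    "replication_adaptation_config",
    "exercise_config",
    "make_trial_plan",
    "run_headless_session",
    "write_records_csv",
    "read_records_csv",
    "records_to_frame",
    "simulate_replication_experiment",
]

# Reference (upper-grating) contrast levels, printed to 4 decimals as used
# in the sessions: 11 geometric steps on [0.02, 0.70]; adaptation uses the
# top 6 of them.
CONTROL_LEVELS: tuple[float, ...] = tuple(np.round(log_spaced(0.02, 0.7, 11), 4))
ADAPTATION_LEVELS: tuple[float, ...] = CONTROL_LEVELS[5:]

CSV_HEADER = [
    "observer_id",
    "mode",
    "condition",
    "trial_index",
    "is_practice",
    "upper_contrast",
    "cut_index",
    "matched_position",
    "matched_contrast",
    "seed",
]


@dataclass(frozen=True)
class SessionConfig:
    """Full description of one session's protocol.

    ``condition`` applies to replication mode only; exercise mode always
    runs practice -> control -> adaptation in order.  Timing fields are in
    seconds and are metadata in headless runs.
    """

    mode: str = "replication"
    condition: str = CONTROL
    contrast_levels: tuple[float, ...] = CONTROL_LEVELS
    reps: int = 10
    adaptation_duration: float = 180.0
    isi: float = 10.0
    topup_contrast: float = 0.7
    n_practice: int = 6
    seed: int = 0
    observer_id: str = "sim"

    def __post_init__(self) -> None:
        if self.mode not in ("replication", "exercise"):
            raise ValueError("mode must be 'replication' or 'exercise'")
        if self.mode == "replication" and self.condition not in (CONTROL, ADAPTATION):
            raise ValueError("condition must be 'control' or 'adaptation'")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not all(0.0 < c <= 1.0 for c in self.contrast_levels):
            raise ValueError("contrast levels must lie in (0, 1]")
        if not 0.0 < self.topup_contrast <= 1.0:
            raise ValueError("topup_contrast must lie in (0, 1]")


def replication_control_config(seed: int = 0, observer_id: str = "sim") -> SessionConfig:
    """110-trial control session: 11 levels x 10 reps, no adaptation."""
    return SessionConfig(
        mode="replication", condition=CONTROL, contrast_levels=CONTROL_LEVELS,
        seed=seed, observer_id=observer_id,
    )


def replication_adaptation_config(seed: int = 0, observer_id: str = "sim") -> SessionConfig:
    """60-trial adaptation session: 6 levels x 10 reps after 180 s adaptation."""
    return SessionConfig(
        mode="replication", condition=ADAPTATION, contrast_levels=ADAPTATION_LEVELS,
        seed=seed, observer_id=observer_id,
    )


def exercise_config(seed: int = 0, observer_id: str = "sim") -> SessionConfig:
    """Seamless classroom session: 6 practice + 60 control + 60 adaptation trials."""
    return SessionConfig(
        mode="exercise", condition=CONTROL, contrast_levels=ADAPTATION_LEVELS,
        seed=seed, observer_id=observer_id,
    )


@dataclass(frozen=True)
class Trial:
    index: int
    condition: str
    upper_contrast: float
    is_practice: bool = False
    cut_index: int | None = None


@dataclass(frozen=True)
class TrialRecord:
    index: int
    condition: str
    upper_contrast: float
    matched_contrast: float
    matched_position: int
    is_practice: bool = False
    cut_index: int | None = None
    observer_id: str = "sim"
    mode: str = "replication"
    seed: int = 0


def make_trial_plan(
    levels: Sequence[float],
    reps: int,
    rng: np.random.Generator,
    condition: str = CONTROL,
    is_practice: bool = False,
    start_index: int = 0,
) -> list[Trial]:
    """Balanced shuffled deck: each level exactly ``reps`` times, uniformly
    random order.  Exact per-level counts are guaranteed by construction."""
    if len(levels) == 0:
        raise ValueError("level list must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    deck = np.repeat(np.asarray(levels, dtype=float), reps)
    deck = deck[rng.permutation(len(deck))]
    return [
        Trial(
            index=start_index + i,
            condition=condition,
            upper_contrast=float(c),
            is_practice=is_practice,
        )
        for i, c in enumerate(deck)
    ]


def _respond(
    trial: Trial,
    observer: ObserverParams,
    scale: ContrastScale,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Simulate one match: draw the intended contrast, clamp it into the
    scale's positive range, quantize onto the log-nearest slider position."""
    intended = simulate_match(observer, trial.condition, trial.upper_contrast, rng)
    if not np.isfinite(intended):
        raise RuntimeError(
            f"observer produced non-finite match {intended!r} on trial "
            f"{trial.index} (condition={trial.condition}, c={trial.upper_contrast})"
        )
    clamped = float(np.clip(intended, scale.min_positive, scale.values.max()))
    pos = nearest_position(scale, clamped)
    return pos, contrast_at(scale, pos)


def run_headless_session(
    config: SessionConfig,
    observer: ObserverParams,
    scale: ContrastScale | None = None,
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Execute a full session against the observer model.

    Replication mode runs the single configured condition on the (never
    rotated) replication scale.  Exercise mode runs practice, control and
    adaptation blocks in that fixed order, drawing a fresh uniform cut for
    the scale on every trial (practice included) and recording it.
    One seeded generator drives trial order, cuts and observer noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    if config.mode == "replication":
        if scale is None:
            scale = build_replication_scale()
        plan = make_trial_plan(config.contrast_levels, config.reps, rng,
                               condition=config.condition)
        records = []
        for trial in plan:
            pos, match = _respond(trial, observer, scale, rng)
            records.append(_record(trial, pos, match, config))
        return records

    # exercise mode
    if scale is None:
        scale = build_exercise_scale()
    if scale.has_zero:
        raise ValueError("exercise mode requires a zero-free (rotatable) scale")
    n_prac_reps, rem = divmod(config.n_practice, len(config.contrast_levels))
    prac_levels = list(config.contrast_levels) * n_prac_reps + list(
        rng.choice(config.contrast_levels, size=rem, replace=False)
    )
    blocks: list[list[Trial]] = []
    idx = 0
    if prac_levels:
        blocks.append(
            make_trial_plan(prac_levels, 1, rng, condition=CONTROL,
                            is_practice=True, start_index=idx)
        )
        idx += len(blocks[-1])
    for condition in (CONTROL, ADAPTATION):
        blocks.append(
            make_trial_plan(config.contrast_levels, config.reps, rng,
                            condition=condition, start_index=idx)
        )
        idx += len(blocks[-1])

    records = []
    for block in blocks:
        for trial in block:
            cut = int(rng.integers(len(scale)))
            trial = replace(trial, cut_index=cut)
            rotated = rotate(scale, cut)
            pos, match = _respond(trial, observer, rotated, rng)
            records.append(_record(trial, pos, match, config))
    return records


def _record(trial: Trial, pos: int, match: float, config: SessionConfig) -> TrialRecord:
    return TrialRecord(
        index=trial.index,
        condition=trial.condition,
        upper_contrast=trial.upper_contrast,
        matched_contrast=match,
        matched_position=pos,
        is_practice=trial.is_practice,
        cut_index=trial.cut_index,
        observer_id=config.observer_id,
        mode=config.mode,
        seed=config.seed,
    )


def simulate_replication_experiment(
    pop,
    rng: np.random.Generator,
    observer_ids: Sequence[str] = ("1", "2"),
) -> list[TrialRecord]:
    """Simulate the full two-condition replication experiment.

    Each observer (drawn from the population model) completes one control
    session (110 trials) and one adaptation session (60 trials) on the
    replication slider.  Session seeds derive from ``rng``.
    """
    from .observer import sample_observer

    records: list[TrialRecord] = []
    for oid in observer_ids:
        obs = sample_observer(pop, rng)
        for factory in (replication_control_config, replication_adaptation_config):
            cfg = factory(seed=int(rng.integers(2**31)), observer_id=str(oid))
            records.extend(run_headless_session(cfg, obs))
    return records


def write_records_csv(records: Iterable[TrialRecord], path) -> None:
    """Write trial records with the fixed schema; floats keep full precision
    (repr round-trips exactly)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.observer_id,
                    r.mode,
                    r.condition,
                    r.index,
                    int(r.is_practice),
                    repr(r.upper_contrast),
                    "" if r.cut_index is None else r.cut_index,
                    r.matched_position,
                    repr(r.matched_contrast),
                    r.seed,
                ]
            )


def read_records_csv(path) -> list[TrialRecord]:
    """Read a trial-record CSV; malformed rows raise with their line number."""
    records: list[TrialRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CSV_HEADER:
            raise ValueError(f"unexpected header {header!r}; expected {CSV_HEADER!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_HEADER):
                raise ValueError(f"line {lineno}: expected {len(CSV_HEADER)} fields, got {len(row)}")
            try:
                records.append(
                    TrialRecord(
                        observer_id=row[0],
                        mode=row[1],
                        condition=row[2],
                        index=int(row[3]),
                        is_practice=bool(int(row[4])),
                        upper_contrast=float(row[5]),
                        cut_index=None if row[6] == "" else int(row[6]),
                        matched_position=int(row[7]),
                        matched_contrast=float(row[8]),
                        seed=int(row[9]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed record: {exc}") from exc
    return records


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Tabular view of records for the analysis layer."""
    records = list(records)
    return pd.DataFrame(
        {
            "observer_id": [r.observer_id for r in records],
            "mode": [r.mode for r in records],
            "condition": [r.condition for r in records],
            "trial_index": [r.index for r in records],
            "is_practice": [r.is_practice for r in records],
            "upper_contrast": [r.upper_contrast for r in records],
            "cut_index": [r.cut_index for r in records],
            "matched_position": [r.matched_position for r in records],
            "matched_contrast": [r.matched_contrast for r in records],
            "seed": [r.seed for r in records],
        }
    )
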