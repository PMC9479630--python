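"""4AFC contrast-increment staircases: adaptive rule, reversals, thresholds.

The task is a four-alternative forced choice: which annulus quadrant carries a
contrast increment on top of a 30% Michelson pedestal.  The increment follows
a transformed 2-up/1-down rule in multiplicative steps of 0.125 log10 units
(two consecutive correct responses make the task harder, one error makes it
easier), which converges at the 70.7%-correct point of the psychometric
function.  A staircase terminates after 12 reversals and its threshold is the
average of the last six reversal increments, taken in the log domain
(geometric mean) to match the multiplicative step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PEDESTAL_CONTRAST = 0.30

#: Columns of the trial-log table shared with the synthetic cohort module.
TRIAL_COLUMNS = ["subject_id", "eye", "ocular_config", "orientation",
                 "surround_contrast", "staircase_id", "trial_index",
                 "increment", "correct"]

CELL_COLUMNS = ["subject_id", "eye", "ocular_config", "orientation",
                "surround_contrast"]


@dataclass
class StaircaseConfig:
    step: float = 0.125                 # log10 units per step
    n_up: int = 2                       # consecutive correct -> decrease increment
    n_down: int = 1                     # incorrect -> increase increment
    stop_reversals: int = 12
    threshold_reversals: int = 6
    start_increment: float = 0.3        # Michelson contrast
    max_trials: int = 400
    floor: float = 1e-4
    ceiling: float = 1.0 - PEDESTAL_CONTRAST
    ceiling_pin_trials: int = 10        # pinned this long -> unmeasurable

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.threshold_reversals > self.stop_reversals:
            raise ValueError("threshold_reversals exceeds stop_reversals")
        if not 0 < self.floor < self.start_increment <= self.ceiling <= 1.0:
            raise ValueError(
                "require 0 < floor < start_increment <= ceiling <= 1")


@dataclass
class StaircaseOutcome:
    reversal_increments: list           # Michelson, in reversal order
    threshold: float | None             # geometric mean of terminal reversals
    converged: bool
    n_trials: int
    unmeasurable: bool = False          # pinned at the response ceiling


@dataclass
class WeibullObserver:
    """4AFC Weibull observer: p(correct) = 0.25 + (0.75 - lapse)(1 - e^-(x/alpha)^beta)."""

    alpha: float
    beta: float = 3.0
    lapse: float = 0.02
    guess: float = 0.25

    def p_correct(self, increment: float) -> float:
        x = max(increment, 0.0)
        return self.guess + (1.0 - self.guess - self.lapse) * (
            1.0 - math.exp(-((x / self.alpha) ** self.beta)))

    def increment_at(self, p: float) -> float:
        """Increment producing proportion-correct ``p`` (inverse psychometric)."""
        frac = (p - self.guess) / (1.0 - self.guess - self.lapse)
        if not 0.0 < frac < 1.0:
            raise ValueError(f"target proportion {p} unattainable")
        return self.alpha * (-math.log(1.0 - frac)) ** (1.0 / self.beta)

    def __call__(self, increment: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_correct(increment))


@dataclass
class StepResponder:
    """Deterministic responder: correct iff increment exceeds its threshold."""

    threshold: float

    def __call__(self, increment: float, rng=None) -> bool:
        return increment > self.threshold


def run_staircase(responder, config: StaircaseConfig = StaircaseConfig(),
                  seed: int | None = 0, cell: dict | None = None,
                  staircase_id: str = "s0"):
    """Run one adaptive staircase against ``responder(increment, rng) -> bool``.

    Returns (trial table, StaircaseOutcome).  The trial table carries the
    columns of the shared trial-log schema; ``cell`` supplies the identifying
    fields (subject, eye, configuration, orientation, surround contrast).
    """
    rng = np.random.default_rng(seed)
    cell = cell or {}
    increment = min(max(config.start_increment, config.floor), config.ceiling)
    streak = 0
    direction = 0                       # +1 harder->easier (up), -1 easier (down)
    reversals = []
    rows = []
    pinned = 0
    unmeasurable = False
    for trial in range(config.max_trials):
        correct = bool(responder(increment, rng))
        rows.append({**cell, "staircase_id": staircase_id, "trial_index": trial,
                     "increment": increment, "correct": correct})
        step_down = step_up = False
        if correct:
            streak += 1
            if streak >= config.n_up:
                streak = 0
                step_down = True
        else:
            streak = 0
            step_up = True
        new_direction = -1 if step_down else (+1 if step_up else direction)
        if new_direction != direction and direction != 0:
            reversals.append(increment)
            if len(reversals) >= config.stop_reversals:
                direction = new_direction
                break
        direction = new_direction
        if step_down:
            increment = max(increment * 10.0 ** (-config.step), config.floor)
        elif step_up:
            increment = min(increment * 10.0 ** (config.step), config.ceiling)
        if increment >= config.ceiling:
            pinned += 1
            if pinned >= config.ceiling_pin_trials:
                unmeasurable = True
                break
        else:
            pinned = 0
    converged = len(reversals) >= config.stop_reversals and not unmeasurable
    outcome = StaircaseOutcome(
        reversal_increments=reversals,
        threshold=estimate_threshold_from_reversals(reversals, config) if converged else None,
        converged=converged, n_trials=len(rows), unmeasurable=unmeasurable)
    trials = pd.DataFrame(rows)
    return trials, outcome


def estimate_threshold_from_reversals(reversals, config: StaircaseConfig) -> float:
    logs = np.log10(reversals[-config.threshold_reversals:])
    return float(10.0 ** logs.mean())


def estimate_threshold(outcome: StaircaseOutcome,
                       config: StaircaseConfig = StaircaseConfig()) -> float:
    """Geometric mean of the last ``threshold_reversals`` reversal increments."""
    if not outcome.converged or len(outcome.reversal_increments) < config.stop_reversals:
        raise ValueError("staircase did not converge; no threshold estimate")
    return estimate_threshold_from_reversals(outcome.reversal_increments, config)


def replay_staircase(trials: pd.DataFrame,
                     config: StaircaseConfig = StaircaseConfig()) -> StaircaseOutcome:
    """Re-derive reversals and threshold from a recorded trial log.

    The adaptive rule is re-applied to the recorded correct/incorrect sequence;
    reversal increments are read from the recorded increments.
    """
    trials = trials.sort_values("trial_index")
    increments = trials["increment"].to_numpy(dtype=float)
    corrects = trials["correct"].to_numpy(dtype=bool)
    streak = 0
    direction = 0
    reversals = []
    for increment, correct in zip(increments, corrects):
        if correct:
            streak += 1
            if streak >= config.n_up:
                streak = 0
                new_direction = -1
            else:
                new_direction = direction
        else:
            streak = 0
            new_direction = +1
        if new_direction != direction and direction != 0:
            reversals.append(float(increment))
            if len(reversals) >= config.stop_reversals:
                direction = new_direction
                break
        direction = new_direction
    converged = len(reversals) >= config.stop_reversals
    return StaircaseOutcome(
        reversal_increments=reversals,
        threshold=(estimate_threshold_from_reversals(reversals, config)
                   if converged else None),
        converged=converged, n_trials=len(increments))


def aggregate_cell(outcomes) -> tuple[float | None, bool]:
    """Cell threshold: geometric mean of converged staircase thresholds.

    Returns (threshold, stable).  ``stable`` is False when fewer than four
    staircases converged; with zero converged the threshold is None (a missing
    cell that propagates downstream).
    """
    thresholds = [o.threshold for o in outcomes if o.converged and o.threshold]
    if not thresholds:
        return None, False
    value = float(10.0 ** np.mean(np.log10(thresholds)))
    return value, len(thresholds) >= 4


def outcomes_from_trials(trials: pd.DataFrame,
                         config: StaircaseConfig = StaircaseConfig()) -> pd.DataFrame:
    """Replay every staircase in a trial log; one row per staircase."""
    rows = []
    for key, group in trials.groupby(CELL_COLUMNS + ["staircase_id"], dropna=False):
        outcome = replay_staircase(group, config)
        rows.append(dict(zip(CELL_COLUMNS + ["staircase_id"], key),
                         threshold=outcome.threshold,
                         converged=outcome.converged,
                         n_trials=outcome.n_trials))
    return pd.DataFrame(rows)


def cell_thresholds(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate staircase outcomes into per-cell thresholds."""
    rows = []
    for key, group in outcomes.groupby(CELL_COLUMNS, dropna=False):
        conv = group[group["converged"] & group["threshold"].notna()]
        if conv.empty:
            value, stable = None, False
        else:
            value = float(10.0 ** np.mean(np.log10(conv["threshold"])))
            stable = len(conv) >= 4
        rows.append(dict(zip(CELL_COLUMNS, key), threshold=value, stable=stable,
                         n_converged=len(conv)))
    return pd.DataFrame(rows)
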