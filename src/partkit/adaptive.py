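"""Adaptive procedures: the two-stage transformed up-down staircase with
unequal step sizes, its analytic convergence target, and the fixed-schedule
progressive tracker used by the speech-on-speech tests.

The staircase is an n-down/1-up rule: the stimulus parameter moves toward
"harder" after ``n_down`` consecutive correct responses and toward "easier"
after any error.  Steps up (easier) are larger than steps down by the
configured ratio, applied in the adaptation domain — as an exponent ratio
for exponentially adapting tracks, additively for linear (dB) tracks.  The
first stage uses large steps for three reversals; the second uses steps 1/5
the size and terminates after six reversals.  The threshold estimate is the
geometric mean of the six second-stage reversal values in native units.

Under a drift-balance analysis this rule converges where the probability of
stepping down equals the up/down size ratio's equilibrium, i.e. at

    p* = (r / (1 + r)) ** (1 / n_down)

so a 2-down/1-up track with a 2:1 ratio targets 81.7% correct and with a
1.5:1 ratio 77.5%, comparable to the 79.4% of a 3-down/1-up equal-step
rule (see :func:`convergence_target`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Scale = Literal["exponential", "linear"]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of a two-stage n-down/1-up track.

    ``stage1_down_step`` is a multiplicative factor (> 1) on the exponential
    scale or an additive dB step on the linear scale; the stage-2 step is
    1/5 the size in the adaptation domain (factor to the 1/5 power, or
    x 1/5 additively).  ``up_down_ratio`` scales the up (easier) step in
    that same domain.  ``increase_on_correct`` flips the orientation for
    tasks whose adaptive parameter grows with difficulty (masker level in
    the tone-in-noise tests).
    """

    start: float
    min_value: float
    max_value: float
    scale: Scale = "exponential"
    n_down: int = 2
    n_up: int = 1
    stage1_down_step: float = 2.0 ** 0.5
    up_down_ratio: float = 2.0
    stage1_reversals: int = 3
    stage2_reversals: int = 6
    increase_on_correct: bool = False

    def __post_init__(self) -> None:
        if not self.min_value < self.start <= self.max_value:
            raise ValueError("need min < start <= max")
        if self.up_down_ratio <= 0:
            raise ValueError("up/down ratio must be positive")
        if self.scale == "exponential" and self.stage1_down_step <= 1.0:
            raise ValueError("exponential step factor must exceed 1")
        if self.scale == "linear" and self.stage1_down_step <= 0.0:
            raise ValueError("linear step must be positive")

    @property
    def stage2_down_step(self) -> float:
        """Stage-2 down step: 1/5 of stage 1 in the adaptation domain."""
        if self.scale == "exponential":
            return self.stage1_down_step ** (1.0 / 5.0)
        return self.stage1_down_step / 5.0

    def down_step(self, stage: int) -> float:
        return self.stage1_down_step if stage == 1 else self.stage2_down_step

    def up_step(self, stage: int) -> float:
        down = self.down_step(stage)
        if self.scale == "exponential":
            return down ** self.up_down_ratio
        return down * self.up_down_ratio


@dataclass
class StaircaseState:
    """Mutable track state: full history, reversals, stage, termination."""

    config: StaircaseConfig
    value: float = field(init=False)
    stage: int = 1
    history: list[tuple[float, bool]] = field(default_factory=list)
    reversals: list[tuple[int, float]] = field(default_factory=list)
    consecutive_correct: int = 0
    finished: bool = False
    _last_direction: int = 0  # +1 easier, -1 harder, 0 none yet

    def __post_init__(self) -> None:
        self.value = self.config.start

    @property
    def n_stage2_reversals(self) -> int:
        return sum(1 for stage, _ in self.reversals if stage == 2)

    def to_rows(self) -> list[dict]:
        """Trial-by-trial log rows (trial, value, correct, stage, reversal)."""
        rows = []
        rev_trials = _reversal_trials(self)
        for i, (value, correct) in enumerate(self.history):
            rows.append(
                {
                    "trial": i + 1,
                    "value": value,
                    "correct": correct,
                    "stage": rev_trials["stages"][i],
                    "reversal": i in rev_trials["trials"],
                }
            )
        return rows

    def to_json(self) -> str:
        return json.dumps(
            {
                "history": [[v, bool(c)] for v, c in self.history],
                "reversals": [[s, v] for s, v in self.reversals],
                "finished": self.finished,
            }
        )


def _reversal_trials(state: StaircaseState) -> dict:
    """Replay the history to tag each trial's stage and reversal status."""
    replayed = StaircaseState(state.config)
    trials: set[int] = set()
    stages: list[int] = []
    for i, (_, correct) in enumerate(state.history):
        stages.append(replayed.stage)
        n_rev = len(replayed.reversals)
        staircase_update(replayed, correct)
        if len(replayed.reversals) > n_rev:
            trials.add(i)
    return {"trials": trials, "stages": stages}


def _apply_step(state: StaircaseState, easier: bool) -> None:
    """Move the parameter one step and do reversal/stage/termination
    bookkeeping.  The logged reversal value is the value *before* the step.
    """
    cfg = state.config
    value_before = state.value

    direction = +1 if easier else -1
    is_reversal = state._last_direction != 0 and direction != state._last_direction
    if is_reversal and state.reversals:
        # A clamped track can oscillate against a bound producing identical
        # consecutive "reversal" values; log such a value at most once.
        last_stage, last_value = state.reversals[-1]
        if (
            last_stage == state.stage
            and last_value == value_before
            and value_before in (cfg.min_value, cfg.max_value)
        ):
            is_reversal = False
    if is_reversal:
        state.reversals.append((state.stage, value_before))
        if state.stage == 1 and len(state.reversals) >= state.config.stage1_reversals:
            state.stage = 2
        elif state.stage == 2 and state.n_stage2_reversals >= cfg.stage2_reversals:
            state.finished = True

    # Step size reflects the reversal just logged: the trial that produces
    # the stage-1-ending reversal already moves by the stage-2 step.
    step = cfg.up_step(state.stage) if easier else cfg.down_step(state.stage)
    # 'easier' maps to a parameter increase unless the track is inverted
    # (masker-level tracks get easier as the parameter decreases).
    increase = easier != cfg.increase_on_correct
    if cfg.scale == "exponential":
        new = value_before * step if increase else value_before / step
    else:
        new = value_before + step if increase else value_before - step
    state._last_direction = direction
    state.value = min(max(new, cfg.min_value), cfg.max_value)


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the track by one scored trial (in place; returns the state).

    After ``n_down`` consecutive correct responses the parameter steps
    toward harder; after any error it steps toward easier by the ratio-scaled
    step.  Direction flips are logged as reversals; the third reversal
    switches to stage 2 and the sixth stage-2 reversal finishes the track.
    """
    if state.finished:
        raise RuntimeError("cannot update a finished track")
    state.history.append((state.value, bool(correct)))
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= state.config.n_down:
            state.consecutive_correct = 0
            _apply_step(state, easier=False)
    else:
        state.consecutive_correct = 0
        _apply_step(state, easier=True)
    return state


def staircase_threshold(state: StaircaseState) -> float:
    """Geometric mean of the second-stage reversal values, in native units."""
    if not state.finished:
        raise RuntimeError("track has not finished")
    values = [v for stage, v in state.reversals if stage == 2][
        : state.config.stage2_reversals
    ]
    if any(v <= 0 for v in values) and state.config.scale == "exponential":
        raise ValueError("nonpositive reversal value under exponential scale")
    return float(np.exp(np.mean(np.log(values))))


def replay(config: StaircaseConfig, responses: list[bool]) -> StaircaseState:
    """Rebuild a track state from a stored response sequence."""
    state = StaircaseState(config)
    for correct in responses:
        staircase_update(state, correct)
    return state


def convergence_target(n_down: int, ratio: float) -> float:
    """Asymptotic percent correct of an n-down/1-up track with unequal steps.

    At equilibrium the expected drift vanishes where the probability of an
    n-long correct run times the down step balances the error-probability
    times the up step, giving ``p* = (r / (1 + r)) ** (1 / n)``.  Returned
    as a percentage.
    """
    if n_down < 1:
        raise ValueError("n_down must be at least 1")
    if ratio <= 0:
        raise ValueError("step ratio must be positive")
    return 100.0 * (ratio / (1.0 + ratio)) ** (1.0 / n_down)


# ---------------------------------------------------------------------------
# Progressive tracking (speech-on-speech / SRM)

@dataclass(frozen=True)
class ProgressiveTrack:
    """Fixed 20-trial schedule: masker level rises 55 to 73 dB SPL in 2-dB
    steps every two trials against a fixed 65-dB-SPL target, giving two
    trials at each of ten target-to-masker ratios from +10 down to -8 dB.
    """

    target_level_db_spl: float = 65.0
    masker_start_db_spl: float = 55.0
    masker_step_db: float = 2.0
    trials_per_level: int = 2
    n_levels: int = 10

    @property
    def n_trials(self) -> int:
        return self.n_levels * self.trials_per_level

    def masker_levels(self) -> np.ndarray:
        """Per-trial masker levels: 55, 55, 57, 57, ..., 73, 73."""
        levels = self.masker_start_db_spl + self.masker_step_db * np.arange(
            self.n_levels
        )
        return np.repeat(levels, self.trials_per_level)

    def tmr_schedule(self) -> np.ndarray:
        """Per-trial target-to-masker ratios, +10 down to -8 dB."""
        return self.target_level_db_spl - self.masker_levels()


def progressive_schedule(cfg: ProgressiveTrack | None = None) -> ProgressiveTrack:
    """Default progressive track (validated)."""
    return cfg if cfg is not None else ProgressiveTrack()


def progressive_score(responses: list[bool] | np.ndarray) -> float:
    """TMR threshold of a progressive session: ``10 - n_correct`` dB.

    Spans +10 dB (no correct responses) to -10 dB (all 20 correct); roughly
    the 50%-correct point of the underlying psychometric function.
    """
    responses = list(responses)
    if len(responses) != ProgressiveTrack().n_trials:
        raise ValueError(f"expected 20 responses, got {len(responses)}")
    return 10.0 - float(sum(bool(r) for r in responses))


def spatial_release(colocated_thr_db: float, separated_thr_db: float) -> float:
    """Spatial release from masking: colocated minus separated TMR threshold.

    Positive values mean spatial separation of the maskers helped; the
    possible range is [-20, 20] dB.
    """
    for thr in (colocated_thr_db, separated_thr_db):
        if not -10.0 <= thr <= 10.0:
            raise ValueError("progressive thresholds lie in [-10, 10] dB")
    return colocated_thr_db - separated_thr_db
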