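"""The ten assessment definitions, screening, practice, and session runner.

The battery comprises three sub-batteries plus a tone-detection screen:

* temporal fine structure — gap, diotic FM, dichotic FM (exponential
  staircases on ms / Hz);
* spectro-temporal modulation — TM, SM, STM (linear staircases on
  mid-to-peak dB depth);
* targets in competition — tone-in-noise without and with a spectral notch
  (linear staircases on masker dB SPL, run first), and the two
  speech-on-speech spatial-release tests (fixed progressive tracks on TMR).

Each two-cue 2AFC assessment runs a two-stage 2-down/1-up staircase with
the step sizes and bounds of the published configuration, preceded by five
non-adaptive practice trials at an easy point in the track.  The session
runner produces a :class:`SessionResult` of native-unit thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .adaptive import (
    ProgressiveTrack,
    StaircaseConfig,
    progressive_score,
    staircase_threshold,
    staircase_update,
    StaircaseState,
)
from .observer import (
    SimulatedObserver,
    adaptation_value,
    respond,
    simulate_progressive,
)

ASSESSMENT_NAMES = (
    "gap",
    "diotic_fm",
    "dichotic_fm",
    "tm",
    "sm",
    "stm",
    "no_notch",
    "notch",
    "srm_colocated",
    "srm_separated",
)

#: Test-type blocks run after the two tone-in-noise tests (which always
#: come first); order within a block is shuffled per participant.
BLOCKS = (
    ("gap", "diotic_fm", "dichotic_fm"),
    ("tm", "sm", "stm"),
    ("srm_colocated", "srm_separated"),
)

N_PRACTICE = 5


@dataclass(frozen=True)
class AssessmentDefinition:
    """One test: stimulus family, adaptive procedure, and units."""

    name: str
    procedure: StaircaseConfig | ProgressiveTrack
    units: str
    stimulus_params: dict = field(default_factory=dict)
    n_practice: int = N_PRACTICE

    @property
    def is_progressive(self) -> bool:
        return isinstance(self.procedure, ProgressiveTrack)


def _exp_staircase(start, min_value, max_value, ratio=2.0) -> StaircaseConfig:
    return StaircaseConfig(
        start=start,
        min_value=min_value,
        max_value=max_value,
        scale="exponential",
        stage1_down_step=2.0 ** 0.5,  # stage 2 is 2**(1/10) via the 1/5 rule
        up_down_ratio=ratio,
    )


def _lin_staircase(
    start, min_value, max_value, step, ratio=2.0, increase_on_correct=False
) -> StaircaseConfig:
    return StaircaseConfig(
        start=start,
        min_value=min_value,
        max_value=max_value,
        scale="linear",
        stage1_down_step=step,
        up_down_ratio=ratio,
        increase_on_correct=increase_on_correct,
    )


def default_battery(up_down_ratio: float = 2.0) -> list[AssessmentDefinition]:
    """The ten assessments with their published parameters.

    ``up_down_ratio`` is 2.0 for the repeatability condition and 1.5 for the
    headphone and noise conditions; it only affects the staircase up-step.
    """
    r = up_down_ratio
    return [
        AssessmentDefinition(
            "gap",
            _exp_staircase(start=20.0, min_value=0.0, max_value=100.0, ratio=r),
            units="ms",
            stimulus_params={"burst_freq": 500.0, "burst_dur_ms": 4.0,
                             "level_db_spl": 80.0},
        ),
        AssessmentDefinition(
            "diotic_fm",
            _exp_staircase(start=6.0, min_value=0.0, max_value=10_000.0, ratio=r),
            units="Hz",
            stimulus_params={"rate_hz": 2.0, "carrier_range": (460.0, 550.0),
                             "duration_ms": 400.0, "level_db_spl": 75.0,
                             "dichotic": False},
        ),
        AssessmentDefinition(
            "dichotic_fm",
            _exp_staircase(start=3.0, min_value=0.0, max_value=10_000.0, ratio=r),
            units="Hz",
            stimulus_params={"rate_hz": 2.0, "carrier_range": (460.0, 550.0),
                             "duration_ms": 400.0, "level_db_spl": 75.0,
                             "dichotic": True},
        ),
        AssessmentDefinition(
            "tm",
            _lin_staircase(start=4.0, min_value=0.2, max_value=40.0, step=0.5,
                           ratio=r),
            units="M (dB)",
            stimulus_params={"tm_rate_hz": 4.0, "sm_density_cpo": 0.0,
                             "level_db_spl": 65.0},
        ),
        AssessmentDefinition(
            "sm",
            _lin_staircase(start=4.0, min_value=0.2, max_value=40.0, step=0.5,
                           ratio=r),
            units="M (dB)",
            stimulus_params={"tm_rate_hz": 0.0, "sm_density_cpo": 2.0,
                             "level_db_spl": 65.0},
        ),
        AssessmentDefinition(
            "stm",
            _lin_staircase(start=4.0, min_value=0.2, max_value=40.0, step=0.5,
                           ratio=r),
            units="M (dB)",
            stimulus_params={"tm_rate_hz": 4.0, "sm_density_cpo": 2.0,
                             "level_db_spl": 65.0},
        ),
        AssessmentDefinition(
            "no_notch",
            _lin_staircase(start=35.0, min_value=25.0, max_value=90.0, step=6.0,
                           ratio=r, increase_on_correct=True),
            units="dB SPL (masker)",
            stimulus_params={"notch": False, "target_freq": 2000.0,
                             "target_level_db_spl": 45.0},
        ),
        AssessmentDefinition(
            "notch",
            _lin_staircase(start=35.0, min_value=25.0, max_value=90.0, step=6.0,
                           ratio=r, increase_on_correct=True),
            units="dB SPL (masker)",
            stimulus_params={"notch": True, "target_freq": 2000.0,
                             "target_level_db_spl": 45.0},
        ),
        AssessmentDefinition(
            "srm_colocated",
            ProgressiveTrack(),
            units="dB TMR",
            stimulus_params={"separated": False},
        ),
        AssessmentDefinition(
            "srm_separated",
            ProgressiveTrack(),
            units="dB TMR",
            stimulus_params={"separated": True},
        ),
    ]


@dataclass
class SessionResult:
    """Per-subject, per-session outcome across the battery."""

    subject_id: str
    session: int
    condition: str = "repeatability"
    thresholds: dict[str, float] = field(default_factory=dict)
    missing: dict[str, str] = field(default_factory=dict)
    passed_screening: bool = True
    screening_correct: int = 10
    trial_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "subject_id": self.subject_id,
                "session": self.session,
                "condition": self.condition,
                "thresholds": self.thresholds,
                "missing": self.missing,
                "passed_screening": self.passed_screening,
                "screening_correct": self.screening_correct,
                "trial_counts": self.trial_counts,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SessionResult":
        d = json.loads(text)
        return cls(**d)


Responder = Callable[[str, float], bool]
"""Answers one trial: (assessment name, adaptation-domain value) -> correct."""


def run_screening(
    responder: Responder | SimulatedObserver, rng: np.random.Generator
) -> tuple[bool, int]:
    """Ten 2AFC trials of a 2-kHz tone at 45 dB SPL; pass needs >= 9 correct.

    A :class:`SimulatedObserver` is treated as hearing the suprathreshold
    screen correctly except for lapses.
    """
    n_correct = 0
    for _ in range(10):
        if isinstance(responder, SimulatedObserver):
            correct = rng.random() < 1.0 - responder.lapse
        else:
            correct = responder("screening", np.inf)
        n_correct += bool(correct)
    return n_correct >= 9, n_correct


def practice_value(config: StaircaseConfig) -> float:
    """Non-adaptive practice point: four stage-1 easier-steps from the start,
    clamped to the track bounds (reproducibly "easily detectable")."""
    value = config.start
    up = config.up_step(1)
    for _ in range(4):
        if config.scale == "exponential":
            value = value * up if not config.increase_on_correct else value / up
        else:
            value = value + up if not config.increase_on_correct else value - up
    return min(max(value, config.min_value), config.max_value)


def _respond_at(
    responder: Responder | SimulatedObserver,
    name: str,
    x: float,
    rng: np.random.Generator,
) -> bool:
    if isinstance(responder, SimulatedObserver):
        return respond(responder, x, rng)
    return bool(responder(name, x))


def run_assessment(
    responder: Responder | SimulatedObserver | dict,
    assessment: AssessmentDefinition,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Practice plus one adaptive or progressive track.

    ``responder`` may be a per-assessment dict of observers.  Returns
    (native-unit threshold, number of scored adaptive trials).  Practice
    trials are presented but never scored into the track.
    """
    if isinstance(responder, dict):
        responder = responder[assessment.name]
    if assessment.is_progressive:
        track = assessment.procedure
        for _ in range(assessment.n_practice):
            _respond_at(responder, assessment.name, track.tmr_schedule()[0], rng)
        responses = [
            _respond_at(responder, assessment.name, tmr, rng)
            for tmr in track.tmr_schedule()
        ]
        return progressive_score(responses), track.n_trials

    config = assessment.procedure
    easy = adaptation_value(config, practice_value(config))
    for _ in range(assessment.n_practice):
        _respond_at(responder, assessment.name, easy, rng)
    state = StaircaseState(config)
    for _ in range(1000):
        if state.finished:
            break
        x = adaptation_value(config, state.value)
        staircase_update(state, _respond_at(responder, assessment.name, x, rng))
    if not state.finished:
        # A responder pinned at ceiling/floor never reverses; report the
        # clamped terminal value (the bound) rather than failing the session.
        thr = min(max(state.value, config.min_value), config.max_value)
        return thr, len(state.history)
    return staircase_threshold(state), len(state.history)


def run_battery(
    responder: Responder | SimulatedObserver | dict,
    battery: list[AssessmentDefinition] | None = None,
    *,
    subject_id: str = "S1",
    session: int = 1,
    condition: str = "repeatability",
    rng: np.random.Generator | None = None,
    require_screening: bool = True,
) -> SessionResult:
    """Run screening and the full battery in the published block order.

    The two tone-in-noise tests always come first; the remaining three
    blocks (TFS, modulation, speech) follow with a seeded shuffle of the
    assessments inside each block.  Unfinished tracks are recorded as
    missing with a reason rather than aborting the session.
    """
    rng = np.random.default_rng() if rng is None else rng
    if battery is None:
        battery = default_battery(2.0 if condition == "repeatability" else 1.5)
    by_name = {a.name: a for a in battery}
    result = SessionResult(subject_id=subject_id, session=session, condition=condition)
    result.passed_screening, result.screening_correct = run_screening(
        responder if not isinstance(responder, dict) else next(iter(responder.values())),
        rng,
    )
    if require_screening and not result.passed_screening:
        return result

    order: list[str] = [n for n in ("no_notch", "notch") if n in by_name]
    for block in BLOCKS:
        names = [n for n in block if n in by_name]
        order.extend(rng.permutation(names).tolist())
    for name in order:
        try:
            thr, n_trials = run_assessment(responder, by_name[name], rng)
            result.thresholds[name] = thr
            result.trial_counts[name] = n_trials
        except RuntimeError as exc:
            result.missing[name] = str(exc)
    return result
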