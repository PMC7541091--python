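"""Parametric simulated listeners for end-to-end procedure verification.

An observer answers two-cue 2AFC trials according to a psychometric
function defined on the task's adaptation domain: log2 of the native
parameter for exponentially adapting tracks, the raw dB value for linear
tracks, and the target-to-masker ratio for the speech tasks.  The default
shape is logistic,

    p(correct | x) = gamma + (1 - gamma - lambda) * F((x - alpha) / beta)

with guess rate ``gamma`` (0.5 for 2AFC), lapse rate ``lambda`` and slope
parameter ``beta`` in adaptation-domain units.  A Weibull option is
provided for detection-style fits.  Observers carry no audio analysis —
they are the harness that lets the staircase, battery and reliability
machinery be exercised without human listeners.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .adaptive import (
    ProgressiveTrack,
    StaircaseConfig,
    StaircaseState,
    progressive_score,
    staircase_threshold,
    staircase_update,
)


@dataclass(frozen=True)
class SimulatedObserver:
    """Psychometric listener on a task's adaptation domain.

    ``alpha`` locates the function (the value where F = 0.5, i.e. 75%
    correct for a lapse-free 2AFC logistic); ``beta`` is the slope scale in
    the same units.  Higher ``x`` must mean an easier trial, so tasks whose
    native parameter shrinks with ease are mapped before calling in.
    """

    alpha: float
    beta: float = 1.0
    gamma: float = 0.5
    lapse: float = 0.02
    shape: Literal["logistic", "weibull"] = "logistic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse rate must lie in [0, 0.5)")
        if self.beta <= 0:
            raise ValueError("slope parameter must be positive")


def percent_correct_at(obs: SimulatedObserver, x: float) -> float:
    """Probability of a correct response at adaptation-domain value ``x``."""
    z = (np.asarray(x, dtype=float) - obs.alpha) / obs.beta
    if obs.shape == "logistic":
        f = expit(z)
    else:
        f = -np.expm1(-np.power(10.0, np.clip(z, None, 300.0)))
    p = obs.gamma + (1.0 - obs.gamma - obs.lapse) * f
    return float(p) if np.isscalar(x) or np.ndim(x) == 0 else p


def threshold_for_percent(obs: SimulatedObserver, percent: float) -> float:
    """Adaptation-domain value where the observer scores ``percent`` correct.

    Root-found numerically; requires gamma*100 < percent < (1-lapse)*100.
    """
    lo, hi = 100.0 * obs.gamma, 100.0 * (1.0 - obs.lapse)
    if not lo < percent < hi:
        raise ValueError(f"percent must lie in ({lo}, {hi})")
    span = 50.0 * obs.beta
    return brentq(
        lambda x: percent_correct_at(obs, x) - percent / 100.0,
        obs.alpha - span,
        obs.alpha + span,
    )


def respond(obs: SimulatedObserver, x: float, rng: np.random.Generator) -> bool:
    """Bernoulli response at the observer's percent-correct for ``x``."""
    return bool(rng.random() < percent_correct_at(obs, x))


def adaptation_value(config: StaircaseConfig, value: float) -> float:
    """Map a native staircase value into the observer's domain.

    Exponential tracks live on log2(native units); linear tracks on the raw
    dB value.  Masker-level tracks (``increase_on_correct``) are negated so
    that larger always means easier.
    """
    if config.scale == "exponential":
        if value <= 0:
            return -np.inf
        x = float(np.log2(value))
    else:
        x = float(value)
    return -x if config.increase_on_correct else x


def simulate_staircase(
    obs: SimulatedObserver,
    config: StaircaseConfig,
    rng: np.random.Generator,
    max_trials: int = 1000,
) -> tuple[float, StaircaseState]:
    """Run one staircase to completion; returns (native threshold, state).

    A responder at ceiling (or floor) never produces reversals, so the
    track cannot finish by the six-reversal rule; after ``max_trials`` the
    current value, clamped to the track bounds, is returned instead (a
    ceiling observer thus terminates at the min bound).  ``state.finished``
    distinguishes the two outcomes.
    """
    state = StaircaseState(config)
    for _ in range(max_trials):
        if state.finished:
            break
        x = adaptation_value(config, state.value)
        staircase_update(state, respond(obs, x, rng))
    if not state.finished:
        return (
            min(max(state.value, config.min_value), config.max_value),
            state,
        )
    return staircase_threshold(state), state


def simulate_progressive(
    obs: SimulatedObserver,
    track: ProgressiveTrack,
    rng: np.random.Generator,
) -> tuple[float, list[bool]]:
    """Run one 20-trial progressive track; returns (TMR threshold, responses).

    The observer is psychometric in TMR directly; its guess rate should be
    1/32 for the color/number response grid.
    """
    responses = [respond(obs, tmr, rng) for tmr in track.tmr_schedule()]
    return progressive_score(responses), responses


def simulate_track(
    obs: SimulatedObserver,
    procedure: StaircaseConfig | ProgressiveTrack,
    rng: np.random.Generator,
) -> tuple[float, StaircaseState | list[bool]]:
    """Dispatch on the procedure type; returns the native-unit threshold."""
    if isinstance(procedure, StaircaseConfig):
        return simulate_staircase(obs, procedure, rng)
    if isinstance(procedure, ProgressiveTrack):
        return simulate_progressive(obs, procedure, rng)
    raise TypeError(f"unsupported procedure: {type(procedure).__name__}")
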