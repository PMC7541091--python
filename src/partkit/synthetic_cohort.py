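"""Seeded two-session cohorts of simulated listeners.

The generator emulates a two-session test-retest study: each subject gets a
true ability (``alpha``) per assessment drawn from a between-subject normal
distribution in analysis units; each session observes that ability plus
within-subject session noise and, for session 2, an optional learning
shift.  A small outlier fraction can be contaminated with large ability
offsets to exercise the 3-SD rejection rule.

Two ways to turn a cohort into a dataset:

* the **threshold-level path** (``simulate_study`` with ``battery=None``)
  emits the session abilities directly as measured thresholds — within-
  subject SD then plays the role of total measurement noise.  This is the
  mode for statistical-recovery experiments, where hundreds of replicate
  cohorts are needed;
* the **full-procedure path** (``battery=`` a battery definition) runs
  every staircase and progressive track through the observer model, so the
  adaptive procedure's own estimation noise enters on top.

Default population parameters are presets chosen to resemble a young
normal-hearing cohort (threshold means/SDs on the analysis scales and
session shifts below 1 dB); they are presets for realistic-looking output,
not fitted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import ANALYSIS_TRANSFORMS, TARGET_LEVEL_DB_SPL, to_analysis_units
from .battery import ASSESSMENT_NAMES, AssessmentDefinition, default_battery, run_battery
from .observer import SimulatedObserver


@dataclass(frozen=True)
class AssessmentPopulation:
    """Population model for one assessment, in analysis units."""

    alpha_mean: float
    alpha_sd: float          # between-subject SD
    session_sd: float        # within-subject (session-to-session) SD
    session2_shift: float = 0.0
    beta: float = 0.5        # observer slope, adaptation-domain units

    def __post_init__(self) -> None:
        if self.alpha_sd < 0 or self.session_sd < 0:
            raise ValueError("SDs must be non-negative")


#: Preset populations (analysis units): log2(ms), log2(Hz), M dB, TMR dB.
DEFAULT_POPULATIONS: dict[str, AssessmentPopulation] = {
    "gap": AssessmentPopulation(1.30, 1.23, 1.11, -0.12, beta=0.5),
    "diotic_fm": AssessmentPopulation(2.67, 0.55, 0.60, -0.06, beta=0.5),
    "dichotic_fm": AssessmentPopulation(-0.97, 0.84, 0.79, 0.01, beta=0.5),
    "tm": AssessmentPopulation(1.55, 0.60, 0.58, -0.13, beta=0.5),
    "sm": AssessmentPopulation(1.61, 0.67, 0.57, -0.16, beta=0.5),
    "stm": AssessmentPopulation(0.95, 0.26, 0.43, 0.01, beta=0.5),
    "no_notch": AssessmentPopulation(-11.43, 1.26, 1.61, -0.83, beta=2.0),
    "notch": AssessmentPopulation(-31.67, 2.18, 2.67, -0.77, beta=2.0),
    "srm_colocated": AssessmentPopulation(2.12, 1.24, 1.55, -0.36, beta=2.0),
    "srm_separated": AssessmentPopulation(-3.91, 2.53, 2.02, -1.12, beta=2.0),
}

#: Inverse analysis-unit transforms (analysis value -> native units).
_INVERSE_TRANSFORMS = {
    "gap": lambda a: 2.0 ** a,
    "diotic_fm": lambda a: 2.0 ** a,
    "dichotic_fm": lambda a: 2.0 ** a,
    "tm": lambda a: a,
    "sm": lambda a: a,
    "stm": lambda a: a,
    "no_notch": lambda a: TARGET_LEVEL_DB_SPL - a,
    "notch": lambda a: TARGET_LEVEL_DB_SPL - a,
    "srm_colocated": lambda a: a,
    "srm_separated": lambda a: a,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study design: cohort size, population models, contamination, lapse."""

    n_subjects: int = 150
    populations: dict[str, AssessmentPopulation] = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS)
    )
    outlier_rate: float = 0.0
    lapse: float = 0.02
    condition: str = "repeatability"

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_rate <= 0.1:
            raise ValueError("outlier rate must lie in [0, 0.1]")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


def generate_cohort(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-subject, per-session observer abilities.

    Returns a long DataFrame (subject, session, assessment, alpha, beta,
    lapse, is_outlier) with ``alpha`` in analysis units.  Outlier subjects
    (per assessment, at ``outlier_rate``) have their true ability displaced
    by 3.5-5 between-subject SDs in either direction, carried into both
    sessions.
    """
    rows = []
    names = list(cfg.populations)
    for name in names:
        pop = cfg.populations[name]
        subject_alpha = rng.normal(pop.alpha_mean, pop.alpha_sd, cfg.n_subjects)
        is_outlier = rng.random(cfg.n_subjects) < cfg.outlier_rate
        if pop.alpha_sd > 0:
            offsets = rng.uniform(3.5, 5.0, cfg.n_subjects) * pop.alpha_sd
            offsets *= rng.choice([-1.0, 1.0], cfg.n_subjects)
            subject_alpha = subject_alpha + np.where(is_outlier, offsets, 0.0)
        for session in (1, 2):
            noise = rng.normal(0.0, pop.session_sd, cfg.n_subjects)
            shift = pop.session2_shift if session == 2 else 0.0
            alphas = subject_alpha + noise + shift
            for i in range(cfg.n_subjects):
                rows.append(
                    {
                        "subject": f"S{i + 1:03d}",
                        "session": session,
                        "assessment": name,
                        "alpha": alphas[i],
                        "beta": pop.beta,
                        "lapse": cfg.lapse,
                        "is_outlier": bool(is_outlier[i]),
                    }
                )
    return pd.DataFrame(rows)


def observer_for(
    name: str, alpha_analysis: float, beta: float, lapse: float
) -> SimulatedObserver:
    """Build the observer whose psychometric location, expressed in analysis
    units, is ``alpha_analysis``.

    The observer domain equals the analysis domain for every task except
    the tone-in-noise pair, whose staircase adapts the masker level: there
    the observer lives on negated masker level, so a TMR-located alpha maps
    to ``alpha - 45``.  Speech-task observers use the 1/32 guess rate of
    the color/number response grid.
    """
    if name in ("no_notch", "notch"):
        return SimulatedObserver(
            alpha=alpha_analysis - TARGET_LEVEL_DB_SPL, beta=beta, lapse=lapse
        )
    if name in ("srm_colocated", "srm_separated"):
        return SimulatedObserver(
            alpha=alpha_analysis, beta=beta, gamma=1.0 / 32.0, lapse=lapse
        )
    return SimulatedObserver(alpha=alpha_analysis, beta=beta, lapse=lapse)


def simulate_study(
    cfg: CohortConfig,
    rng: np.random.Generator,
    battery: list[AssessmentDefinition] | None = None,
) -> pd.DataFrame:
    """Produce the long-format two-session dataset for the analysis module.

    With ``battery=None`` the session abilities are emitted directly as
    measured thresholds (threshold-level path).  With a battery, each
    subject-session runs the full set of adaptive procedures through the
    observer model (full-procedure path; far slower).  Columns match the
    analysis module's input schema: subject, session, condition,
    assessment, value (native units), units, analysis_value.
    """
    cohort = generate_cohort(cfg, rng)
    if battery is None:
        out = cohort.rename(columns={"alpha": "analysis_value"}).copy()
        out["value"] = [
            _INVERSE_TRANSFORMS[name](v)
            for name, v in zip(out["assessment"], out["analysis_value"])
        ]
        out["units"] = [ANALYSIS_TRANSFORMS[n][0] for n in out["assessment"]]
        out["condition"] = cfg.condition
        return out[
            ["subject", "session", "condition", "assessment", "value", "units",
             "analysis_value", "is_outlier"]
        ]

    rows = []
    for (subject, session), group in cohort.groupby(["subject", "session"]):
        observers = {
            r.assessment: observer_for(r.assessment, r.alpha, r.beta, r.lapse)
            for r in group.itertuples()
        }
        result = run_battery(
            observers,
            battery,
            subject_id=str(subject),
            session=int(session),
            condition=cfg.condition,
            rng=rng,
        )
        for name, value in result.thresholds.items():
            rows.append(
                {
                    "subject": subject,
                    "session": session,
                    "condition": cfg.condition,
                    "assessment": name,
                    "value": value,
                }
            )
    native = pd.DataFrame(rows)
    out = to_analysis_units(native)
    out["units"] = out["analysis_units"]
    return out
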