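"""Test-retest reliability pipeline: unit transforms, outlier rejection,
Bland-Altman limits of agreement, and composite scoring.

Thresholds arrive in each test's native units and are first mapped to
analysis units: log2(ms) for the gap test, log2(Hz) for the FM tests,
mid-to-peak dB depth unchanged for the modulation tests, and
target-to-masker ratio (target level minus masker level) for the
tone-in-noise tests; the speech-task thresholds are TMRs already.

Reliability per assessment is summarized by the Bland-Altman bias (mean
session-2 minus session-1 difference) with 95% limits of agreement at
±1.96 SD of the differences, alongside the Pearson correlation, a paired
t-test, and the paired Cohen's d.  Battery-level performance is the
per-subject mean of per-assessment z-scores, with internal consistency
summarized by Cronbach's alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

TARGET_LEVEL_DB_SPL = 45.0  # tone-in-noise target level for the TMR transform

#: Native-unit -> analysis-unit transforms per assessment.
ANALYSIS_TRANSFORMS: dict[str, tuple[str, Callable[[float], float]]] = {
    "gap": ("log2 (ms)", np.log2),
    "diotic_fm": ("log2 (Hz)", np.log2),
    "dichotic_fm": ("log2 (Hz)", np.log2),
    "tm": ("M (dB)", lambda v: v),
    "sm": ("M (dB)", lambda v: v),
    "stm": ("M (dB)", lambda v: v),
    "no_notch": ("TMR (dB)", lambda v: TARGET_LEVEL_DB_SPL - v),
    "notch": ("TMR (dB)", lambda v: TARGET_LEVEL_DB_SPL - v),
    "srm_colocated": ("TMR (dB)", lambda v: v),
    "srm_separated": ("TMR (dB)", lambda v: v),
}


def eq1_convert(m: float | np.ndarray) -> float | np.ndarray:
    """Convert mid-to-peak log-scale depth ``m`` (dB) to 20*log10(m) units.

    The modulation applied here is sinusoidal on a dB amplitude scale with
    depth measured mid-to-peak; much of the literature instead reports
    20*log10 of a linear modulation index m in [0, 1].  The exact bridge is

        20 * log10((10**(m/10) - 1) / (10**(m/10) + 1))

    which is strictly increasing, always negative, and tends to 0 from
    below as m grows.  Raises for m <= 0 (the limit is -inf).
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr <= 0):
        raise ValueError("depth must be positive (limit at 0+ is -inf)")
    r = 10.0 ** (m_arr / 10.0)
    out = 20.0 * np.log10((r - 1.0) / (r + 1.0))
    return float(out) if np.ndim(m) == 0 else out


def to_analysis_units(
    data: pd.DataFrame, value_col: str = "value"
) -> pd.DataFrame:
    """Map native-unit thresholds to analysis units.

    Expects long format with at least ``assessment`` and ``value`` columns.
    Rows whose value cannot be log-transformed (nonpositive under a log2
    transform) are flagged ``excluded`` with a reason rather than dropped.
    """
    out = data.copy()
    values = np.full(len(out), np.nan)
    units = np.empty(len(out), dtype=object)
    excluded = np.empty(len(out), dtype=object)
    excluded[:] = ""
    for i, (assessment, value) in enumerate(
        zip(out["assessment"], out[value_col])
    ):
        if assessment not in ANALYSIS_TRANSFORMS:
            raise KeyError(f"unknown assessment {assessment!r}")
        unit, fn = ANALYSIS_TRANSFORMS[assessment]
        units[i] = unit
        if fn in (np.log2,) and value <= 0:
            excluded[i] = "nonpositive value under log transform"
            continue
        values[i] = fn(value)
    out["analysis_value"] = values
    out["analysis_units"] = units
    out["excluded"] = excluded
    return out


def reject_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Inclusion mask: keep x iff |x - mean| <= k * SD (single pass).

    Mean and sample SD are computed from all values including the
    candidates; the boundary is inclusive (only deviations strictly greater
    than k SD are rejected).  With zero variance and any deviant value the
    rule degenerates to keeping the modal value only.  The rule is a single
    pass by design — re-applying it to the survivors may reject more.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.ones(values.size, dtype=bool)
    return np.abs(values - values.mean()) <= k * sd


@dataclass(frozen=True)
class LoAResult:
    """Bland-Altman agreement plus companion statistics for one assessment."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    r: float
    r_p: float
    t: float
    t_p: float
    d: float
    n: int

    @property
    def df(self) -> int:
        return self.n - 1


def bland_altman(s1: np.ndarray, s2: np.ndarray) -> LoAResult:
    """Agreement between paired sessions: bias, 95% LoA, r, paired t, d.

    ``bias`` is mean(s2 - s1), so for threshold-type measures a negative
    bias means better performance on the second session.  The limits of
    agreement are bias ± 1.96 SD of the paired differences (sample SD).
    Cohen's d is the paired effect size, bias / SD(diff).
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("sessions must be paired (equal length)")
    if s1.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = s2 - s1
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.allclose(s1, s1[0]) or np.allclose(s2, s2[0]):
        r, r_p = np.nan, np.nan
    else:
        r, r_p = stats.pearsonr(s1, s2)
    if sd <= 1e-12 * max(1.0, abs(bias)):
        t, t_p, d = 0.0, 1.0, 0.0
    else:
        t, t_p = stats.ttest_rel(s2, s1)
        d = bias / sd
    return LoAResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        r=float(r),
        r_p=float(r_p),
        t=float(t),
        t_p=float(t_p),
        d=float(d),
        n=int(s1.size),
    )


@dataclass
class CompositeResult:
    """Battery-level scores: per-subject mean z and internal consistency."""

    z_matrix: pd.DataFrame
    composite: pd.Series
    cronbach_alpha: float


def composite_scores(threshold_matrix: pd.DataFrame) -> CompositeResult:
    """Column-wise z-scores, row-wise mean composite, and Cronbach's alpha.

    ``threshold_matrix`` is subjects x assessments in analysis units.
    Missing cells are excluded pairwise (column statistics use available
    values; a subject's composite averages their available z-scores).
    """
    if threshold_matrix.shape[0] < 2 or threshold_matrix.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 assessments")
    sds = threshold_matrix.std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero-variance assessment(s): {list(zero.index)}")
    z = (threshold_matrix - threshold_matrix.mean()) / sds
    alpha = float(
        pg.cronbach_alpha(data=z.dropna(axis=0, how="any"))[0]
    )
    return CompositeResult(
        z_matrix=z, composite=z.mean(axis=1), cronbach_alpha=alpha
    )


def loa_plot_data(s1: np.ndarray, s2: np.ndarray) -> pd.DataFrame:
    """Per-subject (mean of sessions, difference) pairs for LoA plots."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    return pd.DataFrame({"mean": (s1 + s2) / 2.0, "diff": s2 - s1})


def test_retest_report(
    dataset: pd.DataFrame,
    *,
    outlier_k: float | None = 3.0,
    value_col: str = "analysis_value",
) -> dict:
    """Full reliability report from a long-format two-session dataset.

    Expects columns ``subject``, ``session`` (1/2), ``assessment`` and the
    analysis-unit value column (run :func:`to_analysis_units` first if the
    data are native).  Per assessment: single-pass 3-SD outlier rejection
    (per session), pairing of subjects seen in both sessions, and a
    :class:`LoAResult` row; subjects with one session are dropped with a
    log entry.  Battery-level composites are computed per session from the
    subjects x assessments matrix, and their agreement is reported on the
    same footing as the individual tests.

    Returns a dict with ``table`` (one row per assessment plus composite),
    ``plot_data`` (LoA scatter input per assessment), ``composites`` (the
    two per-session :class:`CompositeResult`), and ``dropped``.
    """
    required = {"subject", "session", "assessment", value_col}
    if not required.issubset(dataset.columns):
        raise ValueError(f"dataset must have columns {sorted(required)}")
    data = dataset.copy()
    if "excluded" in data.columns:
        data = data[data["excluded"].astype(str) == ""]
    data = data.dropna(subset=[value_col])

    rows = []
    plot_data: dict[str, pd.DataFrame] = {}
    dropped: list[str] = []
    wide_by_session: dict[int, pd.DataFrame] = {}
    assessments = [a for a in ANALYSIS_TRANSFORMS if a in set(data["assessment"])]

    kept = []
    for name in assessments:
        sub = data[data["assessment"] == name]
        for session in (1, 2):
            s = sub[sub["session"] == session].copy()
            if outlier_k is not None and len(s) >= 3:
                mask = reject_outliers(s[value_col].to_numpy(), k=outlier_k)
                s = s[mask]
            kept.append(s)
    data = pd.concat(kept, ignore_index=True)

    for session in (1, 2):
        wide_by_session[session] = data[data["session"] == session].pivot_table(
            index="subject", columns="assessment", values=value_col
        )

    for name in assessments:
        w1, w2 = wide_by_session[1], wide_by_session[2]
        if name not in w1.columns or name not in w2.columns:
            continue
        pair = pd.concat(
            [w1[name].rename("s1"), w2[name].rename("s2")], axis=1
        )
        incomplete = pair[pair.isna().any(axis=1)].index
        dropped.extend(f"{name}:{s}" for s in incomplete)
        pair = pair.dropna()
        res = bland_altman(pair["s1"].to_numpy(), pair["s2"].to_numpy())
        unit = ANALYSIS_TRANSFORMS[name][0]
        rows.append(_table_row(name, unit, res))
        plot_data[name] = loa_plot_data(
            pair["s1"].to_numpy(), pair["s2"].to_numpy()
        )

    # Composite: subjects with complete batteries in both sessions.
    comps: dict[int, CompositeResult] = {}
    common = wide_by_session[1].dropna().index.intersection(
        wide_by_session[2].dropna().index
    )
    if len(common) >= 3 and len(assessments) >= 2:
        for session in (1, 2):
            comps[session] = composite_scores(
                wide_by_session[session].loc[common, assessments]
            )
        res = bland_altman(
            comps[1].composite.to_numpy(), comps[2].composite.to_numpy()
        )
        rows.append(_table_row("composite", "z", res))
        plot_data["composite"] = loa_plot_data(
            comps[1].composite.to_numpy(), comps[2].composite.to_numpy()
        )

    table = pd.DataFrame(rows).set_index("test")
    return {
        "table": table,
        "plot_data": plot_data,
        "composites": comps,
        "dropped": dropped,
    }


# not a pytest test, despite the name
test_retest_report.__test__ = False  # type: ignore[attr-defined]


def _table_row(name: str, unit: str, res: LoAResult) -> dict:
    return {
        "test": name,
        "bias": res.bias,
        "loa_low": res.loa_low,
        "loa_high": res.loa_high,
        "units": unit,
        "r": res.r,
        "r_p": res.r_p,
        "t": res.t,
        "t_p": res.t_p,
        "cohens_d": res.d,
        "df": res.df,
    }


def notch_separation(no_notch_tmr: float, notch_tmr: float) -> float:
    """Distance between the no-notch and notch TMR thresholds (dB).

    An index of cochlear frequency resolution: how much protection the
    800-Hz spectral notch affords the 2-kHz target.
    """
    return abs(no_notch_tmr - notch_tmr)
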