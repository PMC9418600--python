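"""Condition-level summaries and significance calls.

Each condition (a temperature or a pH value) carries n replicate activity
scores; conditions are summarised as mean +/- SEM and compared against the
inactive control condition (10 degC, or pH 2) with a two-sided, pooled
equal-variance Student's t-test.  Stars follow the usual convention:
``*`` p < 0.05, ``**`` p < 0.01, no multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import InsufficientDataError, InvalidParameterError

__all__ = ["ConditionSummary", "summarize", "t_test_vs_control", "condition_profile"]

P_STAR = 0.05
P_DOUBLE_STAR = 0.01


@dataclass(frozen=True)
class ConditionSummary:
    condition_value: float
    mean_activity: float
    sem: float
    n: int
    t_statistic: float | None = None
    p_value_vs_control: float | None = None

    @property
    def significance(self) -> str:
        p = self.p_value_vs_control
        if p is None:
            return ""
        if p < P_DOUBLE_STAR:
            return "**"
        if p < P_STAR:
            return "*"
        return ""


def summarize(scores: Sequence[float], condition_value: float) -> ConditionSummary:
    """Mean and SEM (= sd / sqrt(n), ddof = 1) of the replicate activities."""
    values = np.asarray(list(scores), dtype=float)
    if values.size == 0:
        raise InvalidParameterError("cannot summarise an empty score list")
    if values.size == 1:
        warnings.warn("single replicate: SEM undefined, reported as 0", stacklevel=2)
        sem = 0.0
    else:
        sem = float(values.std(ddof=1) / np.sqrt(values.size))
    return ConditionSummary(
        condition_value=float(condition_value),
        mean_activity=float(values.mean()),
        sem=sem,
        n=int(values.size),
    )


def t_test_vs_control(
    group: Sequence[float], control: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test (pooled variance by default).

    Welch's unequal-variance form is available via ``equal_var=False``.
    Degenerate input with zero variance in both groups returns p = 1 when the
    means agree (no evidence of a difference) and p = 0 otherwise.
    """
    g = np.asarray(list(group), dtype=float)
    c = np.asarray(list(control), dtype=float)
    if g.size < 2 or c.size < 2:
        raise InsufficientDataError("each group needs n >= 2 for a t-test")
    if g.std(ddof=1) == 0.0 and c.std(ddof=1) == 0.0:
        if g.mean() == c.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(g.mean() - c.mean()), 0.0
    t, p = scipy.stats.ttest_ind(g, c, equal_var=equal_var)
    return float(t), float(p)


def condition_profile(
    series: Mapping[float, Sequence[float]],
    control_value: float,
    equal_var: bool = True,
) -> list[ConditionSummary]:
    """One summary per condition, each tested against the control condition.

    ``series`` maps condition value -> replicate activity scores.  The
    control's own p-value is set to 1 by convention.
    """
    if control_value not in series:
        raise InvalidParameterError(f"control condition {control_value} missing from series")
    control_scores = series[control_value]
    out: list[ConditionSummary] = []
    for value in sorted(series):
        base = summarize(series[value], value)
        if value == control_value:
            t, p = 0.0, 1.0
        else:
            t, p = t_test_vs_control(series[value], control_scores, equal_var=equal_var)
        out.append(
            ConditionSummary(
                condition_value=base.condition_value,
                mean_activity=base.mean_activity,
                sem=base.sem,
                n=base.n,
                t_statistic=t,
                p_value_vs_control=p,
            )
        )
    return out


def profile_to_frame(profile: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Summary table in the output CSV dialect."""
    return pd.DataFrame(
        {
            "condition": [s.condition_value for s in profile],
            "mean": [s.mean_activity for s in profile],
            "sem": [s.sem for s in profile],
            "n": [s.n for s in profile],
            "t": [s.t_statistic for s in profile],
            "p": [s.p_value_vs_control for s in profile],
            "significance": [s.significance for s in profile],
        }
    )
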