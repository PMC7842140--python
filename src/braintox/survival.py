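"""Kaplan-Meier estimation and log-rank comparison for censored cohorts.

Event = sacrifice for radiation-induced health deterioration; censoring =
reaching the follow-up horizon event-free.  The estimator and the
Mantel-Haenszel log-rank test are delegated to :mod:`lifelines`; ties are
handled jointly at each distinct event time with hypergeometric variance,
and censoring at an event time counts after the event (the standard
convention, which lifelines follows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = ["SurvivalRecord", "km_curve", "logrank_test"]


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-animal follow-up time (weeks) and event flag (1=event, 0=censored)."""

    mouse_id: str
    group_label: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"{self.mouse_id}: survival time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"{self.mouse_id}: event must be 0 or 1, got {self.event}")


def km_curve(records: Sequence[SurvivalRecord]) -> List[Tuple[float, float]]:
    """Product-limit survivor function as a list of (time, S(time)) steps.

    Starts at (0, 1); probabilities drop only at event times, censored
    times reduce the risk set only.
    """
    recs = list(records)
    if not recs:
        raise ValueError("km_curve requires a non-empty record list")
    times = [r.time for r in recs]
    events = [r.event for r in recs]
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    curve = [(float(t), float(s)) for t, s in sf.items()]
    if not curve or curve[0][0] != 0.0:
        curve.insert(0, (0.0, 1.0))
    return curve


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> Tuple[float, float]:
    """Two-group Mantel-Haenszel log-rank test.

    Returns the chi-square statistic (1 df) and its p-value.  Undefined
    when neither group has any event.
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in a) and not any(r.event for r in b):
        raise ValueError("log-rank statistic undefined: no events in either group")
    res = _lifelines_logrank(
        np.array([r.time for r in a]),
        np.array([r.time for r in b]),
        event_observed_A=np.array([r.event for r in a]),
        event_observed_B=np.array([r.event for r in b]),
    )
    return float(res.test_statistic), float(res.p_value)
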