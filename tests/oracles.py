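"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and libraries) they check:
survival statistics are computed by explicit risk-table enumeration, and
the growth law is inverted by direct arithmetic.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

from scipy.stats import chi2


def km_oracle(times: Sequence[float], events: Sequence[int]) -> List[Tuple[float, float]]:
    """Product-limit estimate by hand: S *= (1 - d/n) at each event time."""
    s = 1.0
    curve = [(0.0, 1.0)]
    for t in sorted(set(times)):
        n_at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        if d > 0:
            s *= 1.0 - d / n_at_risk
            curve.append((t, s))
    return curve


def logrank_oracle(
    times_a: Sequence[float], events_a: Sequence[int],
    times_b: Sequence[float], events_b: Sequence[int],
) -> Tuple[float, float]:
    """Mantel-Haenszel log-rank by risk-table enumeration.

    At each distinct event time: observed events in group A minus the
    hypergeometric expectation, with the hypergeometric variance; ties are
    handled jointly, censoring at an event time stays in the risk set.
    """
    all_times = sorted(set(list(times_a) + list(times_b)))
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        na = sum(1 for ti in times_a if ti >= t)
        nb = sum(1 for ti in times_b if ti >= t)
        da = sum(1 for ti, ei in zip(times_a, events_a) if ti == t and ei == 1)
        db = sum(1 for ti, ei in zip(times_b, events_b) if ti == t and ei == 1)
        n, d = na + nb, da + db
        if d == 0 or n == 0:
            continue
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var == 0.0:
        return float("nan"), float("nan")
    stat = o_minus_e**2 / var
    return stat, float(chi2.sf(stat, df=1))
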