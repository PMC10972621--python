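"""Kaplan–Meier estimation and the two-group log-rank test.

Both are implemented from their definitions: the product-limit estimator
S(t) = prod_{t_i <= t} (1 - d_i / n_i) with events preceding censoring at
tied times, and the log-rank statistic (sum O - sum E)^2 / sum V with the
hypergeometric mean and variance accumulated over distinct event times,
referred to chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = ["km_estimate", "logrank_test", "KMCurve"]


def _check_table(surv: pd.DataFrame) -> None:
    for col in ("time", "event"):
        if col not in surv.columns:
            raise ValueError(f"survival table lacks the {col!r} column")
    if (surv["time"] < 0).any():
        raise ValueError("negative follow-up times")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")


@dataclass
class KMCurve:
    """Product-limit curve over the distinct event times of one stratum."""

    table: pd.DataFrame  # time, n_at_risk, n_events, survival
    stratum: str | None = None

    def survival_at(self, t: float) -> float:
        tab = self.table[self.table["time"] <= t]
        return 1.0 if tab.empty else float(tab["survival"].iloc[-1])


def km_estimate(surv: pd.DataFrame, stratum: str | None = None) -> KMCurve:
    """Kaplan–Meier estimate, optionally restricted to one stratum label."""
    _check_table(surv)
    sub = surv if stratum is None else surv[surv["stratum"] == stratum]
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} is empty")
    times = sub["time"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)
    event_times = np.unique(times[events == 1])
    rows, s = [], 1.0
    for t in event_times:
        n_at_risk = int((times >= t).sum())  # censored at t still at risk for events at t
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        rows.append((float(t), n_at_risk, d, s))
    table = pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])
    return KMCurve(table=table, stratum=stratum)


def logrank_test(surv: pd.DataFrame, stratum_a: str, stratum_b: str) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    _check_table(surv)
    sub = surv[surv["stratum"].isin([stratum_a, stratum_b])]
    a = sub["stratum"] == stratum_a
    if a.sum() == 0 or (~a).sum() == 0:
        raise ValueError("both strata must be non-empty")
    if sub["event"].sum() == 0:
        raise ValueError("log-rank statistic undefined with zero events")
    times = sub["time"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)
    in_a = a.to_numpy()

    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_a).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in_a).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        raise ValueError("log-rank variance is zero (no informative event time)")
    stat = o_minus_e ** 2 / var
    return float(stat), float(st.chi2.sf(stat, df=1))
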