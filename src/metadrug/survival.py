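"""Kaplan-Meier estimation and two-group log-rank comparison.

Group definition follows the median-split convention: samples with
biomarker expression strictly above the median are "high", the rest "low".
Ties of events and censorings at the same time are resolved events-first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SurvivalCurve", "km_curve", "log_rank_test", "median_split_survival"]


@dataclass
class SurvivalCurve:
    """Product-limit estimate: one row per distinct event time."""

    table: pd.DataFrame  # columns: time, n_risk, n_event, survival

    def survival_at(self, t: float) -> float:
        past = self.table[self.table["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


def km_curve(clinical: pd.DataFrame) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator from (os_months, os_event)."""
    if clinical.empty:
        raise ValueError("clinical table is empty")
    times = clinical["os_months"].to_numpy(float)
    events = clinical["os_event"].to_numpy(int)
    if (times <= 0).any():
        raise ValueError("nonpositive survival times present")
    event_times = np.unique(times[events == 1])
    rows = []
    s = 1.0
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_risk
        rows.append((t, n_risk, d, s))
    return SurvivalCurve(
        pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "survival"])
    )


def log_rank_test(clinical: pd.DataFrame, groups: pd.Series | np.ndarray) -> dict:
    """Two-group log-rank test with hypergeometric variance.

    Returns chi2 (1 df), p, and observed/expected events in group 1.
    """
    times = clinical["os_months"].to_numpy(float)
    events = clinical["os_event"].to_numpy(int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 nonempty groups, got {len(labels)}")
    in1 = g == labels[0]
    if events.sum() == 0:
        warnings.warn("no events observed; log-rank undefined, p = 1", stacklevel=2)
        return {"chi2": 0.0, "p_value": 1.0, "observed": 0.0, "expected": 0.0}
    o_minus_e = 0.0
    var = 0.0
    observed = 0.0
    expected = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        nj = int(at_risk.sum())
        n1j = int((at_risk & in1).sum())
        dj = int(((times == t) & (events == 1)).sum())
        d1j = int(((times == t) & (events == 1) & in1).sum())
        e1j = dj * n1j / nj
        observed += d1j
        expected += e1j
        o_minus_e += d1j - e1j
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if var == 0:
        chi2 = 0.0
    else:
        chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return {"chi2": chi2, "p_value": p, "observed": observed, "expected": expected}


def median_split_survival(
    expr: pd.DataFrame,
    gene: str,
    clinical: pd.DataFrame,
) -> tuple[SurvivalCurve, SurvivalCurve, dict, pd.Series]:
    """Split samples at the median expression of one gene (ties go low),
    return KM curves for low/high, the log-rank result and the labels."""
    if gene not in expr.index:
        raise ValueError(f"gene {gene!r} not in expression matrix")
    matched = clinical[clinical["sample_id"].isin(expr.columns)].reset_index(drop=True)
    if matched.empty:
        raise ValueError("no samples shared between expression and clinical table")
    values = expr.loc[gene, matched["sample_id"]].to_numpy(float)
    med = np.median(values)
    if np.ptp(values) == 0:
        raise ValueError(f"gene {gene!r} has constant expression; split undefined")
    labels = pd.Series(
        np.where(values > med, "high", "low"),
        index=matched["sample_id"],
        name="expression_group",
    )
    low = matched[labels.to_numpy() == "low"]
    high = matched[labels.to_numpy() == "high"]
    if low.empty or high.empty:
        raise ValueError("median split produced an empty group")
    result = log_rank_test(matched, labels.to_numpy())
    return km_curve(low), km_curve(high), result, labels
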