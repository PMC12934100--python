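"""Outcome stratification: Kaplan-Meier, log-rank and response chi-square.

Samples are stratified by the dormancy label (score > 0 -> dormant) and
compared on survival (product-limit curves, two-sample log-rank with
statistic (sum O - sum E)^2 / sum V on 1 df) and on categorical therapy
response (Pearson chi-square on the group x response contingency table,
no continuity correction by default).  Tied event and censoring times
follow the standard convention: events precede censorings, i.e. subjects
censored at t remain at risk for events at t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = ["KMCurve", "km_estimate", "logrank_test", "response_chisq", "response_table"]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival after each distinct observed time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def _check_survival(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table needs a '{col}' column")
    times = df["time"].to_numpy(dtype=float)
    if not np.all(np.isfinite(times)):
        raise ValueError("survival times must be finite")
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    events = df["event"].to_numpy()
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("event must be 0 (censored) or 1 (event)")
    return df


def km_estimate(df: pd.DataFrame, group=None, group_col: str = "group") -> KMCurve:
    """Kaplan-Meier curve for one group (or the whole table when group is None)."""
    df = _check_survival(df)
    if group is not None:
        df = df[df[group_col] == group]
    if len(df) == 0:
        raise ValueError(f"no subjects in group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    table = kmf.event_table.iloc[1:] if 0.0 not in set(df["time"]) else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)
    return KMCurve(times=times, survival=survival, at_risk=at_risk)


def logrank_test(df: pd.DataFrame, group_col: str = "group") -> tuple[float, float, int]:
    """Two-sample log-rank test; returns (statistic, p, df=1)."""
    df = _check_survival(df)
    if group_col not in df.columns:
        raise ValueError(f"survival table needs a '{group_col}' column")
    groups = sorted(df[group_col].astype(str).unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {groups}")
    a = df[df[group_col].astype(str) == groups[0]]
    b = df[df[group_col].astype(str) == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if int(df["event"].sum()) == 0:
        raise ValueError("log-rank statistic undefined with zero events")
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value), 1


def response_table(
    groups: pd.Series, responses: pd.Series
) -> pd.DataFrame:
    """Group x response contingency counts from per-sample labels."""
    groups = pd.Series(groups).astype(str)
    responses = pd.Series(responses).astype(str).reindex(groups.index)
    if responses.isna().any():
        raise ValueError("responses must cover every grouped sample")
    return pd.crosstab(groups, responses)


def response_chisq(table: pd.DataFrame, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table; returns (chi2, df, p).

    No Yates continuity correction by default; set ``correction=True`` to
    apply it on 2x2 tables.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("contingency counts must be non-negative integers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    res = stats.chi2_contingency(counts, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)
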