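"""Median-split stratification, Kaplan-Meier curves, and log-rank tests.

The estimator and test are the standard product-limit and two-group
log-rank (hypergeometric variance with tie multiplicities), provided by
``lifelines`` behind this module's interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    n_a: int
    n_b: int
    df: int = 1


def median_split(features: pd.Series | np.ndarray) -> pd.Series:
    """Label each patient ``high`` (feature > median) or ``low`` (<= median).

    Ties at the median go to the low group.  Requires >= 4 patients and
    a non-constant feature.
    """
    values = pd.Series(features).astype(float)
    if len(values) < 4:
        raise ValueError("median split needs >= 4 patients")
    if values.nunique() == 1:
        raise ValueError("feature is constant; median split undefined")
    med = values.median()
    return pd.Series(np.where(values > med, "high", "low"), index=values.index, name="group")


def km_estimate(times: np.ndarray | pd.Series, events: np.ndarray | pd.Series) -> pd.DataFrame:
    """Product-limit survival curve with risk-set sizes.

    Returns one row per observed time: ``time``, ``n_at_risk``,
    ``n_events``, ``n_censored``, ``survival``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "n_at_risk": table["at_risk"].to_numpy(dtype=int),
            "n_events": table["observed"].to_numpy(dtype=int),
            "n_censored": table["censored"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    )
    return out[out["time"] > 0].reset_index(drop=True) if 0 not in times else out.reset_index(drop=True)


def logrank(
    times_a: np.ndarray | pd.Series,
    events_a: np.ndarray | pd.Series,
    times_b: np.ndarray | pd.Series,
    events_b: np.ndarray | pd.Series,
) -> LogRankResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both arms must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined without any events")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        n_a=len(ta),
        n_b=len(tb),
    )


def median_split_logrank(table: pd.DataFrame, feature_col: str = "feature") -> dict:
    """Convenience wrapper: median-split a feature column and test the strata.

    ``table`` needs ``time``, ``event`` and the feature column; returns
    the group labels, KM curves per stratum, and the log-rank result.
    """
    for col in ("time", "event", feature_col):
        if col not in table.columns:
            raise ValueError(f"survival table lacks column {col!r}")
    groups = median_split(table[feature_col])
    high = groups == "high"
    result = logrank(
        table.loc[high, "time"],
        table.loc[high, "event"],
        table.loc[~high, "time"],
        table.loc[~high, "event"],
    )
    return {
        "groups": groups,
        "km_high": km_estimate(table.loc[high, "time"], table.loc[high, "event"]),
        "km_low": km_estimate(table.loc[~high, "time"], table.loc[~high, "event"]),
        "logrank": result,
    }
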