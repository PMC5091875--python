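"""Kaplan-Meier estimation and k-sample log-rank testing.

These wrap lifelines, which implements the product-limit estimator and the
log-rank chi-square with the standard hypergeometric variance correction
for tied event times, so results are directly comparable with mainstream
survival software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io_formats import ClinicalTable

__all__ = ["SurvivalRecord", "LogrankResult", "km_estimate", "logrank_test"]

SIGNIFICANCE_DEFAULT = 0.05


@dataclass(frozen=True)
class SurvivalRecord:
    """One sample's follow-up: time in days and death indicator."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.sample_id}: survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def _coerce_records(
    records: Sequence[SurvivalRecord] | ClinicalTable,
) -> pd.DataFrame:
    if isinstance(records, ClinicalTable):
        df = records.data[["survival_time", "event"]].copy()
        df.columns = ["time", "event"]
        return df
    return pd.DataFrame(
        {"time": [r.time for r in records], "event": [r.event for r in records]},
        index=[r.sample_id for r in records],
    )


def km_estimate(records: Sequence[SurvivalRecord] | ClinicalTable) -> pd.DataFrame:
    """Product-limit survival curve.

    Returns a DataFrame with columns ``time``, ``survival`` and ``at_risk``;
    the estimate starts at 1 and is non-increasing, with right-censored
    samples leaving the risk set without an event.
    """
    df = _coerce_records(records)
    if df.empty:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(float), "survival": surv.to_numpy(float),
         "at_risk": at_risk.to_numpy(float)}
    ).reset_index(drop=True)


def logrank_test(
    records: Sequence[SurvivalRecord] | ClinicalTable,
    groups: Mapping[str, object] | pd.Series,
) -> LogrankResult:
    """k-sample log-rank test for equal survival across groups.

    ``groups`` maps sample id to a group label; the statistic is
    chi-square distributed with (number of groups - 1) degrees of freedom
    under the null.
    """
    df = _coerce_records(records)
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.reindex(df.index)
    if groups.isna().any():
        missing = list(df.index[groups.isna()])[:5]
        raise ValueError(f"samples without a group label: {missing}")
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(df["time"], groups, df["event"])
    stat = float(res.test_statistic)
    return LogrankResult(statistic=max(stat, 0.0), df=n_groups - 1, p_value=float(res.p_value))


def km_to_tsv(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, sep="\t", index=False)
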