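"""Transmission-rate metrics, reminder-call decomposition, weekday tables,
and adherent/nonadherent cohort classification.

All multi-day rates are patient-day proportions (micro-averages): a single
numerator and denominator pooled over the patient-days in scope, matching the
single-denominator transmission-rate formula (100 x transmitting patient-days
/ patient-days in scope) rather than a mean of per-patient rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import IRT, ORT, ObservationTable, month_of
from .stats_util import descriptive

__all__ = [
    "EmptyScopeError",
    "AdherenceSummary",
    "MonthlyRates",
    "WeekdayTable",
    "WEEKDAY_ORDER",
    "transmission_rate",
    "monthly_rates",
    "weekday_table",
    "missed_call_rate",
    "percent_in_range",
    "classify_cohorts",
    "adherence_threshold_days",
]

# published weekday tables run Sunday..Saturday
WEEKDAY_ORDER = ["Sunday", "Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday"]


class EmptyScopeError(ValueError):
    """A rate was requested over a scope containing no eligible patient-days."""


@dataclass(frozen=True)
class AdherenceSummary:
    """Pre/post reminder-call transmission rates over one scope (percent)."""

    scope: str
    n_patients: int
    rate_pre: float
    rate_post: float
    call_gain: float  # rate_post - rate_pre: transmissions attributable to the call
    pct_no_transmit_after_call: float  # of called days, still not transmitting
    pct_missed_call: float  # of pre-deadline-missed days, no call attempted


@dataclass
class MonthlyRates:
    """Five monthly summaries plus the month-1 -> month-5 rate drops."""

    summaries: pd.DataFrame  # one row per month, AdherenceSummary fields
    pre_drop: float
    post_drop: float


@dataclass
class WeekdayTable:
    """Post-call adherence percent per 30-day month x weekday, with a
    per-weekday mean and population-SD summary row."""

    by_month: pd.DataFrame  # index month 1..5, columns Sunday..Saturday
    mean: pd.Series
    sd: pd.Series  # population convention (divide by n)


def _scoped(table: ObservationTable, patient_ids=None, month: int | None = None) -> pd.DataFrame:
    df = table.data
    if patient_ids is not None:
        df = df[df["patient_id"].isin(set(patient_ids))]
    if month is not None:
        df = df[month_of(df["study_day"]) == month]
    return df


def transmission_rate(
    table: ObservationTable,
    when: str = "post",
    patient_ids=None,
    month: int | None = None,
) -> float:
    """Percent of patient-days in scope with a transmission.

    ``when="pre"`` counts transmissions received before the patient's daily
    deadline; ``"post"`` counts transmissions received by end of day
    (including those rescued by a reminder call).
    """
    if when not in ("pre", "post"):
        raise ValueError("when must be 'pre' or 'post'")
    df = _scoped(table, patient_ids, month)
    if df.empty:
        raise EmptyScopeError("no patient-days in scope")
    return 100.0 * float(df[f"transmitted_{when}"].mean())


def missed_call_rate(table: ObservationTable, patient_ids=None, month: int | None = None) -> float:
    """Percent of pre-deadline-missed days on which no reminder call was
    attempted."""
    df = _scoped(table, patient_ids, month)
    missed = df[~df["transmitted_pre"]]
    if missed.empty:
        raise EmptyScopeError("no pre-deadline-missed days in scope")
    return 100.0 * float((~missed["call_attempted"]).mean())


def percent_in_range(table: ObservationTable, patient_ids=None, month: int | None = None) -> float:
    """Percent of transmissions in scope that were in range:
    100 x #IRT / (#IRT + #ORT).  Non-transmitting days are excluded."""
    if "event" not in table.data.columns:
        raise ValueError("table has no 'event' column; run classify_events first")
    df = _scoped(table, patient_ids, month)
    n_irt = int((df["event"] == IRT).sum())
    n_ort = int((df["event"] == ORT).sum())
    if n_irt + n_ort == 0:
        raise EmptyScopeError("no transmissions in scope")
    return 100.0 * n_irt / (n_irt + n_ort)


def _summary(df: pd.DataFrame, scope: str) -> AdherenceSummary:
    if df.empty:
        raise EmptyScopeError(f"no patient-days in scope {scope!r}")
    rate_pre = 100.0 * float(df["transmitted_pre"].mean())
    rate_post = 100.0 * float(df["transmitted_post"].mean())
    called = df[df["call_attempted"]]
    pct_fail = (
        100.0 * float((~called["transmitted_post"]).mean()) if len(called) else float("nan")
    )
    missed = df[~df["transmitted_pre"]]
    pct_missed_call = (
        100.0 * float((~missed["call_attempted"]).mean()) if len(missed) else float("nan")
    )
    return AdherenceSummary(
        scope=scope,
        n_patients=int(df["patient_id"].nunique()),
        rate_pre=rate_pre,
        rate_post=rate_post,
        call_gain=rate_post - rate_pre,
        pct_no_transmit_after_call=pct_fail,
        pct_missed_call=pct_missed_call,
    )


def monthly_rates(table: ObservationTable, patient_ids=None) -> MonthlyRates:
    """Per-month adherence summaries over the trimmed analysis window.

    Months are 30-day blocks of renumbered study days.  Also reports the
    month-1 -> month-5 drop of the pre- and post-call rates.
    """
    if table.analysis_days is None:
        raise ValueError("monthly_rates expects a washout-trimmed table")
    n_months = table.analysis_days // 30
    df = _scoped(table, patient_ids)
    if df.empty:
        raise EmptyScopeError("no patient-days in scope")
    months = month_of(df["study_day"])
    rows = []
    for m in range(1, n_months + 1):
        s = _summary(df[months == m], scope=f"month {m}")
        rows.append(
            {
                "month": m,
                "n_patients": s.n_patients,
                "rate_pre": s.rate_pre,
                "rate_post": s.rate_post,
                "call_gain": s.call_gain,
                "pct_no_transmit_after_call": s.pct_no_transmit_after_call,
                "pct_missed_call": s.pct_missed_call,
            }
        )
    summaries = pd.DataFrame(rows).set_index("month")
    pre_drop = float(summaries.loc[1, "rate_pre"] - summaries.loc[n_months, "rate_pre"])
    post_drop = float(summaries.loc[1, "rate_post"] - summaries.loc[n_months, "rate_post"])
    return MonthlyRates(summaries=summaries, pre_drop=pre_drop, post_drop=post_drop)


def overall_summary(table: ObservationTable, patient_ids=None, scope: str = "overall") -> AdherenceSummary:
    """Single pooled adherence summary over all patient-days in scope."""
    return _summary(_scoped(table, patient_ids), scope)


def weekday_table(table: ObservationTable, patient_ids=None) -> WeekdayTable:
    """Post-call adherence percent per (30-day month, calendar weekday).

    Cells with zero patient-days are flagged absent (NaN).  The summary row
    is the arithmetic mean and population SD of each weekday's month cells.
    """
    if table.analysis_days is None:
        raise ValueError("weekday_table expects a washout-trimmed table")
    n_months = table.analysis_days // 30
    df = _scoped(table, patient_ids)
    if df.empty:
        raise EmptyScopeError("no patient-days in scope")
    months = month_of(df["study_day"])
    weekdays = pd.to_datetime(df["date"]).dt.day_name()
    cell = (
        df.assign(month=months, weekday=weekdays)
        .groupby(["month", "weekday"], observed=True)["transmitted_post"]
        .mean()
        .mul(100.0)
        .unstack("weekday")
        .reindex(index=range(1, n_months + 1), columns=WEEKDAY_ORDER)
    )
    means, sds = {}, {}
    for wd in WEEKDAY_ORDER:
        col = cell[wd].dropna()
        if len(col):
            means[wd], sds[wd] = descriptive(col, sd_convention="population")
        else:
            means[wd], sds[wd] = float("nan"), float("nan")
    return WeekdayTable(
        by_month=cell,
        mean=pd.Series(means)[WEEKDAY_ORDER],
        sd=pd.Series(sds)[WEEKDAY_ORDER],
    )


def adherence_threshold_days(threshold: float, analysis_days: int) -> int:
    """Minimum transmitted days for the adherent label: ceil(threshold x days),
    computed robustly against binary-float artifacts (0.8 x 150 = 120)."""
    return int(math.ceil(threshold * analysis_days - 1e-9))


def classify_cohorts(table: ObservationTable, threshold: float = 0.8) -> pd.Series:
    """Label each patient adherent / nonadherent by post-call transmitted days.

    A patient is adherent when they transmitted on at least
    ``ceil(threshold x analysis_days)`` days (inclusive boundary: 120 of 150
    at the default 80% threshold).
    """
    if table.analysis_days is None:
        raise ValueError("classify_cohorts expects a washout-trimmed table")
    need = adherence_threshold_days(threshold, table.analysis_days)
    transmitted = table.data.groupby("patient_id", sort=True)["transmitted_post"].sum()
    labels = np.where(transmitted >= need, "adherent", "nonadherent")
    return pd.Series(labels, index=transmitted.index, name="cohort")
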