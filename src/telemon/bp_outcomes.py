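"""Month-1 vs month-5 blood-pressure change analysis.

Per patient and 30-day month, the mean systolic and diastolic pressure over
transmitted days is computed; patients missing either month entirely are
excluded.  The change score is month-1 minus month-5, so a *positive* value
means the pressure fell (improvement).  Per-cohort significance uses a
two-tailed paired t test on the change scores; the between-cohort comparison
uses a two-tailed independent t test (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import ObservationTable, month_of
from .stats_util import descriptive, independent_t, paired_t

__all__ = [
    "MonthlyVitalsMean",
    "BPChangeResult",
    "BPChangeComparison",
    "monthly_bp_means",
    "bp_change_analysis",
    "uncontrolled_subgroup",
]

# re-exported name for the record type of monthly_bp_means rows
MonthlyVitalsMean = ["patient_id", "month", "sbp_mean", "dbp_mean", "n_readings"]


@dataclass(frozen=True)
class BPChangeResult:
    """Month-1 minus month-5 change summary for one cohort."""

    cohort: str
    vital: str
    n_included: int
    n_excluded_missing_month: int
    mean_change: float  # mm Hg, positive = improvement
    sd_change: float  # sample (n-1) convention
    p_paired: float | None  # None when degenerate (zero variance)


@dataclass
class BPChangeComparison:
    """Per-cohort change results plus the between-cohort independent t."""

    vital: str
    results: dict[str, BPChangeResult]
    p_between: float | None
    n_subgroup: int | None = None  # set by uncontrolled_subgroup


def monthly_bp_means(table: ObservationTable) -> pd.DataFrame:
    """Per patient-month mean vitals over transmitted days.

    Months with zero transmissions yield no record at all (the missingness
    rule that later excludes the patient from the paired analysis).
    """
    df = table.data
    tx = df[df["transmitted_post"]]
    if tx.empty:
        return pd.DataFrame(columns=MonthlyVitalsMean)
    g = tx.assign(month=month_of(tx["study_day"])).groupby(["patient_id", "month"], sort=True)
    out = g.agg(sbp_mean=("sbp", "mean"), dbp_mean=("dbp", "mean"), n_readings=("sbp", "size"))
    return out.reset_index()


def _changes(
    means: pd.DataFrame, patient_ids, vital: str, month_first: int, month_last: int
) -> tuple[pd.Series, int]:
    """Per-patient change scores (first minus last) and the count excluded
    for missing either month."""
    sub = means[means["patient_id"].isin(set(patient_ids))]
    col = f"{vital}_mean"
    wide = sub.pivot(index="patient_id", columns="month", values=col)
    for m in (month_first, month_last):
        if m not in wide.columns:
            wide[m] = np.nan
    both = wide[[month_first, month_last]].dropna()
    changes = both[month_first] - both[month_last]
    n_excluded = len(set(patient_ids)) - len(changes)
    return changes, n_excluded


def bp_change_analysis(
    means: pd.DataFrame,
    cohorts: pd.Series,
    vital: str = "sbp",
    month_first: int = 1,
    month_last: int = 5,
    welch: bool = True,
    skip_small: bool = False,
) -> BPChangeComparison:
    """Month-1 vs month-5 change analysis per cohort.

    ``means`` comes from :func:`monthly_bp_means`; ``cohorts`` maps
    patient_id -> cohort label.  Only patients with records in both months
    are included.  A cohort with fewer than 2 eligible patients is an error
    unless ``skip_small`` (used for small subgroups) drops it instead.
    """
    if vital not in ("sbp", "dbp"):
        raise ValueError("vital must be 'sbp' or 'dbp'")
    results: dict[str, BPChangeResult] = {}
    change_lists: dict[str, pd.Series] = {}
    for cohort in pd.unique(cohorts):
        members = cohorts.index[cohorts == cohort]
        changes, n_excluded = _changes(means, members, vital, month_first, month_last)
        if len(changes) < 2:
            if skip_small:
                continue
            raise ValueError(f"cohort {cohort!r} has fewer than 2 patients with both months")
        mean_c, sd_c = descriptive(changes, sd_convention="sample")
        t = paired_t(changes)
        results[cohort] = BPChangeResult(
            cohort=str(cohort),
            vital=vital,
            n_included=len(changes),
            n_excluded_missing_month=n_excluded,
            mean_change=mean_c,
            sd_change=sd_c,
            p_paired=t.p_value,
        )
        change_lists[cohort] = changes
    p_between = None
    if len(change_lists) == 2:
        a, b = change_lists.values()
        p_between = independent_t(a, b, welch=welch).p_value
    return BPChangeComparison(vital=vital, results=results, p_between=p_between)


def uncontrolled_subgroup(
    means: pd.DataFrame,
    cohorts: pd.Series,
    vital: str = "sbp",
    sbp_cut: float = 140.0,
    dbp_cut: float = 90.0,
    combine: str = "and",
    month_first: int = 1,
    month_last: int = 5,
    welch: bool = True,
) -> BPChangeComparison:
    """Change analysis restricted to month-1 uncontrolled hypertension.

    The subgroup holds patients whose month-1 mean SBP is strictly above
    ``sbp_cut`` *and* month-1 mean DBP strictly above ``dbp_cut``
    (``combine="or"`` gives the disjunctive guideline-style variant).  An
    empty subgroup returns an explicit empty result rather than an error;
    cohorts with fewer than 2 subgroup members are dropped.
    """
    m1 = means[means["month"] == month_first]
    if combine == "and":
        mask = (m1["sbp_mean"] > sbp_cut) & (m1["dbp_mean"] > dbp_cut)
    elif combine == "or":
        mask = (m1["sbp_mean"] > sbp_cut) | (m1["dbp_mean"] > dbp_cut)
    else:
        raise ValueError("combine must be 'and' or 'or'")
    subgroup_ids = set(m1.loc[mask, "patient_id"])
    if not subgroup_ids:
        return BPChangeComparison(vital=vital, results={}, p_between=None, n_subgroup=0)
    sub_cohorts = cohorts[cohorts.index.isin(subgroup_ids)]
    cmp = bp_change_analysis(
        means[means["patient_id"].isin(subgroup_ids)],
        sub_cohorts,
        vital=vital,
        month_first=month_first,
        month_last=month_last,
        welch=welch,
        skip_small=True,
    )
    cmp.n_subgroup = len(subgroup_ids)
    return cmp
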