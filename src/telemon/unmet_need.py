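"""Unmet-need estimation: missed monitoring days whose readings would have
been out of range.

If the out-of-range fraction observed among transmitted days also applies to
the days when no reading was transmitted, the expected number of missed
out-of-range days per patient over a monitoring window is

    (1 - post_rate) x oor_fraction x days,

a lost-follow-up-opportunity count.  The cohort total reproduces the printed
reporting convention exactly: per-patient values are rounded to two decimals
before being multiplied by cohort sizes and summed, and the overall
percentage is recomputed from the total rather than copied.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .adherence_metrics import percent_in_range, transmission_rate
from .io_model import ObservationTable
from .stats_util import round_half_away

__all__ = [
    "UnmetNeedEstimate",
    "per_patient_unmet_days",
    "total_unmet_days",
    "estimate_unmet_need",
]


@dataclass
class UnmetNeedEstimate:
    """Per-cohort and overall unmet-need summary."""

    per_cohort: pd.DataFrame  # cohort, n_patients, post_rate, oor_fraction, per_patient_days(, _reported)
    total_days: int
    overall_pct: float  # percent of all patient-days in the window
    days: int


def per_patient_unmet_days(post_rate: float, oor_fraction: float, days: int = 150) -> float:
    """Expected missed out-of-range days per patient (unrounded).

    ``post_rate`` is the post-call transmission rate as a fraction,
    ``oor_fraction`` the out-of-range fraction of transmissions.  The
    one-decimal value quoted in reports is a rounding of this return value.
    """
    for name, val in (("post_rate", post_rate), ("oor_fraction", oor_fraction)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    if days <= 0:
        raise ValueError("days must be positive")
    return (1.0 - post_rate) * oor_fraction * days


def total_unmet_days(per_cohort: list[tuple[float, int]], days: int = 150) -> tuple[int, float]:
    """Total unmet-need days over cohorts, and the overall percentage.

    Each ``(per_patient_days, cohort_size)`` pair is combined as
    round2(per_patient_days) x size; the sum is rounded to the nearest day.
    The percentage is 100 x total / (days x total patients).
    """
    total = 0.0
    n_total = 0
    for per_patient, size in per_cohort:
        if size <= 0:
            raise ValueError("cohort sizes must be positive")
        total += round_half_away(per_patient, 2) * size
        n_total += size
    total_days = int(round_half_away(total, 0))
    overall_pct = 100.0 * total_days / (days * n_total)
    return total_days, overall_pct


def estimate_unmet_need(
    table: ObservationTable, cohorts: pd.Series, days: int | None = None
) -> UnmetNeedEstimate:
    """Apply the estimator to measured per-cohort rates of a classified table."""
    if days is None:
        if table.analysis_days is None:
            raise ValueError("days not given and table is not washout-trimmed")
        days = table.analysis_days
    rows = []
    pairs = []
    for cohort in sorted(pd.unique(cohorts)):
        members = cohorts.index[cohorts == cohort]
        post = transmission_rate(table, "post", patient_ids=members) / 100.0
        oor = 1.0 - percent_in_range(table, patient_ids=members) / 100.0
        per_patient = per_patient_unmet_days(post, oor, days)
        rows.append(
            {
                "cohort": cohort,
                "n_patients": len(members),
                "post_rate": post,
                "oor_fraction": oor,
                "per_patient_days": per_patient,
                "per_patient_days_reported": round_half_away(per_patient, 2),
            }
        )
        pairs.append((per_patient, len(members)))
    total_days, overall_pct = total_unmet_days(pairs, days=days)
    return UnmetNeedEstimate(
        per_cohort=pd.DataFrame(rows),
        total_days=total_days,
        overall_pct=overall_pct,
        days=days,
    )
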