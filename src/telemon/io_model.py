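"""Domain types, CSV input/output, eligibility filtering, washout trimming,
and per-day transmission-event classification.

The unit of analysis is the *patient-day*.  Each monitored day ends in exactly
one of three transmission events:

``NT``
    no transmission was received by end of day;
``ORT``
    a transmission was received but at least one vital (systolic BP,
    diastolic BP, pulse) fell strictly outside the patient's
    physician-assigned alert range;
``IRT``
    a transmission was received with all three vitals inside the range
    (bounds inclusive: a reading equal to a bound is in range).

Two transmission flags are kept per day: ``transmitted_pre`` (the reading
arrived before the patient's self-selected daily deadline) and
``transmitted_post`` (the reading arrived by end of day, possibly rescued by a
staff reminder call).  The day's event is always judged on the post-call
status; the pre-call flag only feeds the pre/post rate decomposition.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EVENTS",
    "NT",
    "ORT",
    "IRT",
    "VITALS",
    "DEFAULT_BOUNDS",
    "PERSONALIZED_LIMITS",
    "AlertRange",
    "Patient",
    "ObservationTable",
    "SchemaError",
    "IntegrityError",
    "DAILY_COLUMNS",
    "PATIENT_COLUMNS",
    "read_daily_records",
    "write_daily_records",
    "read_patients",
    "write_patients",
    "alert_ranges_from_patients",
    "filter_eligible",
    "apply_washout",
    "month_of",
    "classify_event",
    "classify_events",
]

NT, ORT, IRT = "NT", "ORT", "IRT"
EVENTS: tuple[str, str, str] = (NT, ORT, IRT)
VITALS: tuple[str, str, str] = ("sbp", "dbp", "pulse")

# physician-assigned acceptable windows; defaults and the limits within which
# personalized (customized) bounds must lie
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "sbp": (90.0, 160.0),
    "dbp": (60.0, 90.0),
    "pulse": (60.0, 120.0),
}
PERSONALIZED_LIMITS: dict[str, tuple[float, float]] = {
    "sbp": (55.0, 200.0),
    "dbp": (50.0, 120.0),
    "pulse": (50.0, 120.0),
}


class SchemaError(ValueError):
    """An input file does not have the documented column layout."""


class IntegrityError(ValueError):
    """Rows violate the daily-record invariants; message lists row numbers."""


@dataclass(frozen=True)
class AlertRange:
    """Acceptable vitals window assigned by the patient's physician.

    A reading is in range when every vital lies inside its ``[low, high]``
    window, bounds inclusive.  Personalized (non-default) bounds must lie
    within the plausible clinical limits 55-200 / 50-120 / 50-120.
    """

    sbp_low: float = DEFAULT_BOUNDS["sbp"][0]
    sbp_high: float = DEFAULT_BOUNDS["sbp"][1]
    dbp_low: float = DEFAULT_BOUNDS["dbp"][0]
    dbp_high: float = DEFAULT_BOUNDS["dbp"][1]
    pulse_low: float = DEFAULT_BOUNDS["pulse"][0]
    pulse_high: float = DEFAULT_BOUNDS["pulse"][1]

    def __post_init__(self) -> None:
        for vital in VITALS:
            low, high = self.bounds(vital)
            if not low < high:
                raise ValueError(f"{vital}: low bound {low} must be < high bound {high}")
            if not self.is_default(vital):
                lim_lo, lim_hi = PERSONALIZED_LIMITS[vital]
                if low < lim_lo or high > lim_hi:
                    raise ValueError(
                        f"{vital}: personalized bounds [{low}, {high}] outside "
                        f"allowed limits [{lim_lo}, {lim_hi}]"
                    )

    def bounds(self, vital: str) -> tuple[float, float]:
        return getattr(self, f"{vital}_low"), getattr(self, f"{vital}_high")

    def is_default(self, vital: str) -> bool:
        return self.bounds(vital) == DEFAULT_BOUNDS[vital]

    def contains(self, sbp: float, dbp: float, pulse: float) -> bool:
        """True when all three vitals are inside the window (inclusive)."""
        for vital, value in zip(VITALS, (sbp, dbp, pulse)):
            low, high = self.bounds(vital)
            if value < low or value > high:
                return False
        return True


@dataclass(frozen=True)
class Patient:
    patient_id: str
    age: float
    sex: str  # {female, male}
    region: str  # {Dallas, Houston, McAllen, SanAntonio}
    urbanicity: str  # {urban, suburban_rural}
    alert_range: AlertRange = field(default_factory=AlertRange)
    enrollment_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")


# canonical column orders for the two CSV interfaces
DAILY_COLUMNS = [
    "patient_id",
    "date",
    "transmitted_pre",
    "call_attempted",
    "transmitted_post",
    "sbp",
    "dbp",
    "pulse",
]
PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "region",
    "urbanicity",
    "sbp_low",
    "sbp_high",
    "dbp_low",
    "dbp_high",
    "pulse_low",
    "pulse_high",
    "enrollment_date",
]


@dataclass
class ObservationTable:
    """Ordered collection of daily observations plus window metadata.

    ``data`` holds one row per patient-day, sorted by (patient_id, study_day),
    with study_day consecutive from 1 within each patient.  ``washout_days``
    and ``analysis_days`` record how the table has been trimmed (0 / None for
    a raw table).  After :func:`classify_events` the frame also carries an
    ``event`` column.
    """

    data: pd.DataFrame
    washout_days: int = 0
    analysis_days: int | None = None

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["patient_id"]))

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    def days_per_patient(self) -> pd.Series:
        return self.data.groupby("patient_id", sort=True).size()

    def with_data(self, data: pd.DataFrame, **meta) -> "ObservationTable":
        kwargs = {"washout_days": self.washout_days, "analysis_days": self.analysis_days}
        kwargs.update(meta)
        return ObservationTable(data, **kwargs)


def _violations(df: pd.DataFrame) -> list[str]:
    """Invariant check on a parsed daily frame; returns human-readable
    messages with 1-based data-row numbers."""
    problems: list[str] = []

    def rows(mask) -> str:
        idx = np.flatnonzero(np.asarray(mask)) + 1
        shown = ", ".join(map(str, idx[:10]))
        more = "" if idx.size <= 10 else f" (+{idx.size - 10} more)"
        return shown + more

    pre_no_post = df["transmitted_pre"] & ~df["transmitted_post"]
    if pre_no_post.any():
        problems.append(f"transmitted_pre without transmitted_post at rows {rows(pre_no_post)}")

    has_all = df[list(VITALS)].notna().all(axis=1)
    has_any = df[list(VITALS)].notna().any(axis=1)
    post_missing_vitals = df["transmitted_post"] & ~has_all
    if post_missing_vitals.any():
        problems.append(
            f"transmitted_post without all three vitals at rows {rows(post_missing_vitals)}"
        )
    vitals_no_post = ~df["transmitted_post"] & has_any
    if vitals_no_post.any():
        problems.append(f"vitals present without transmitted_post at rows {rows(vitals_no_post)}")

    for pid, grp in df.groupby("patient_id", sort=False):
        if grp["date"].duplicated().any():
            problems.append(f"patient {pid}: duplicate dates")
        elif not grp["date"].is_monotonic_increasing:
            problems.append(f"patient {pid}: dates not strictly increasing")
    return problems


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    """Sort, derive study_day, and normalize dtypes of a parsed daily frame."""
    df = df.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    df["study_day"] = df.groupby("patient_id", sort=False).cumcount() + 1
    for flag in ("transmitted_pre", "call_attempted", "transmitted_post"):
        df[flag] = df[flag].astype(bool)
    for vital in VITALS:
        df[vital] = pd.to_numeric(df[vital], errors="coerce").astype(float)
    cols = ["patient_id", "date", "study_day"] + [
        c for c in DAILY_COLUMNS if c not in ("patient_id", "date")
    ]
    return df[cols]


def read_daily_records(path) -> ObservationTable:
    """Read a daily-records CSV into an :class:`ObservationTable`.

    The file must carry the documented header (``patient_id, date,
    transmitted_pre, call_attempted, transmitted_post, sbp, dbp, pulse``) with
    ISO-8601 dates and blank vitals on non-transmitting days.  All invariant
    violations are collected and raised together as :class:`IntegrityError`
    with offending row numbers.  Late spontaneous transmissions (post without
    pre and without a call) are permitted but logged.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"daily records file {path} missing columns: {missing}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.normalize()
    for flag in ("transmitted_pre", "call_attempted", "transmitted_post"):
        vals = pd.to_numeric(df[flag], errors="raise")
        if not vals.isin((0, 1)).all():
            raise SchemaError(f"column {flag} must be 0/1")
        df[flag] = vals.astype(bool)
    problems = _violations(df)
    if problems:
        raise IntegrityError("; ".join(problems))
    late = df["transmitted_post"] & ~df["transmitted_pre"] & ~df["call_attempted"]
    if late.any():
        logger.warning(
            "%d late spontaneous transmission(s): received post-deadline with no reminder call",
            int(late.sum()),
        )
    return ObservationTable(_finalize(df))


def write_daily_records(table: ObservationTable, path) -> None:
    """Write a daily-records CSV (UTF-8, deterministic column order).

    Vitals are written as integers when whole-valued, blank when absent; the
    write -> read round trip is lossless on such tables.
    """
    df = table.data.copy()
    out = pd.DataFrame()
    out["patient_id"] = df["patient_id"]
    out["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    for flag in ("transmitted_pre", "call_attempted", "transmitted_post"):
        out[flag] = df[flag].astype(int)
    for vital in VITALS:
        v = df[vital]
        whole = v.dropna().mod(1).eq(0).all()
        out[vital] = v.astype("Int64") if whole else v
    out.to_csv(path, index=False)


def read_patients(path) -> pd.DataFrame:
    """Read a patient table CSV; validates alert-range bounds row by row."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"patient file {path} missing columns: {missing}")
    if df["patient_id"].duplicated().any():
        dupes = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"].unique())
        raise IntegrityError(f"duplicate patient_id(s): {dupes[:10]}")
    if (df["age"] <= 0).any():
        raise IntegrityError("non-positive ages present")
    df["enrollment_date"] = pd.to_datetime(df["enrollment_date"], format="ISO8601").dt.normalize()
    alert_ranges_from_patients(df)  # bound validation
    return df[PATIENT_COLUMNS].sort_values("patient_id", kind="mergesort").reset_index(drop=True)


def write_patients(patients: pd.DataFrame, path) -> None:
    out = patients.copy()
    out["enrollment_date"] = pd.to_datetime(out["enrollment_date"]).dt.strftime("%Y-%m-%d")
    for col in ("sbp_low", "sbp_high", "dbp_low", "dbp_high", "pulse_low", "pulse_high"):
        if out[col].mod(1).eq(0).all():
            out[col] = out[col].astype(int)
    out[PATIENT_COLUMNS].to_csv(path, index=False)


def alert_ranges_from_patients(patients: pd.DataFrame) -> dict[str, AlertRange]:
    """Map patient_id -> :class:`AlertRange`, validating each row's bounds."""
    ranges: dict[str, AlertRange] = {}
    for row in patients.itertuples(index=False):
        ranges[row.patient_id] = AlertRange(
            sbp_low=float(row.sbp_low),
            sbp_high=float(row.sbp_high),
            dbp_low=float(row.dbp_low),
            dbp_high=float(row.dbp_high),
            pulse_low=float(row.pulse_low),
            pulse_high=float(row.pulse_high),
        )
    return ranges


def filter_eligible(table: ObservationTable, min_days: int = 180) -> tuple[ObservationTable, int]:
    """Keep patients with at least ``min_days`` consecutive monitored days.

    Returns the filtered table and the number of excluded patients.  The
    boundary is inclusive: exactly ``min_days`` days qualifies.
    """
    days = table.days_per_patient()
    keep = days.index[days >= min_days]
    n_excluded = int((days < min_days).sum())
    data = table.data[table.data["patient_id"].isin(keep)].reset_index(drop=True)
    logger.info("eligibility filter: retained %d of %d patients", len(keep), len(days))
    return table.with_data(data), n_excluded


def apply_washout(
    table: ObservationTable, washout_days: int = 30, analysis_days: int = 150
) -> ObservationTable:
    """Drop the startup period and trim to the analysis window.

    Per patient, study days 1..``washout_days`` are removed, the remaining
    days renumbered 1..``analysis_days`` and truncated beyond that.  Months
    are thereafter defined as 30-day blocks of renumbered days (see
    :func:`month_of`).  A patient with fewer than ``washout_days +
    analysis_days`` days is an error naming the patient.
    """
    need = washout_days + analysis_days
    days = table.days_per_patient()
    short = days.index[days < need]
    if len(short):
        raise ValueError(
            f"patients with fewer than {need} days cannot be trimmed: "
            + ", ".join(map(str, short[:10]))
        )
    df = table.data
    mask = (df["study_day"] > washout_days) & (df["study_day"] <= need)
    out = df.loc[mask].copy()
    out["study_day"] = out["study_day"] - washout_days
    out = out.reset_index(drop=True)
    return ObservationTable(out, washout_days=washout_days, analysis_days=analysis_days)


def month_of(study_day) -> "pd.Series | int | np.ndarray":
    """30-day-block month index of a renumbered study day (day 1-30 -> month 1)."""
    if isinstance(study_day, pd.Series):
        return (study_day - 1) // 30 + 1
    return (np.asarray(study_day) - 1) // 30 + 1 if np.ndim(study_day) else (int(study_day) - 1) // 30 + 1


def classify_event(
    transmitted_post: bool,
    sbp: float | None,
    dbp: float | None,
    pulse: float | None,
    alert_range: AlertRange,
) -> str:
    """Classify one patient-day into NT / ORT / IRT.

    ``NT`` when no transmission was received by end of day; ``ORT`` when any
    vital is strictly outside its ``[low, high]`` window; ``IRT`` otherwise
    (bounds inclusive).
    """
    if not transmitted_post:
        return NT
    if sbp is None or dbp is None or pulse is None or any(
        isinstance(v, float) and math.isnan(v) for v in (sbp, dbp, pulse)
    ):
        raise ValueError("transmitted day must carry all three vitals")
    return IRT if alert_range.contains(sbp, dbp, pulse) else ORT


def classify_events(table: ObservationTable, patients: pd.DataFrame) -> ObservationTable:
    """Vectorized per-day event classification; adds an ``event`` column.

    ``patients`` supplies each patient's alert-range bounds.  Every patient in
    the table must appear in the patient table.
    """
    df = table.data
    missing = set(df["patient_id"]) - set(patients["patient_id"])
    if missing:
        raise IntegrityError(f"patients without alert ranges: {sorted(missing)[:10]}")
    bound_cols = ["patient_id", "sbp_low", "sbp_high", "dbp_low", "dbp_high", "pulse_low", "pulse_high"]
    merged = df.merge(patients[bound_cols], on="patient_id", how="left", sort=False)
    out_of_range = np.zeros(len(merged), dtype=bool)
    for vital in VITALS:
        v = merged[vital]
        out_of_range |= (v < merged[f"{vital}_low"]) | (v > merged[f"{vital}_high"])
    event = np.where(~merged["transmitted_post"], NT, np.where(out_of_range, ORT, IRT))
    data = df.copy()
    data["event"] = pd.Categorical(event, categories=list(EVENTS))
    return table.with_data(data)
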