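"""Shared fixtures: compact hand-built observation tables and a small
session-scoped synthetic cohort."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from telemon.adherence_metrics import classify_cohorts
from telemon.io_model import (
    DAILY_COLUMNS,
    ObservationTable,
    apply_washout,
    classify_events,
    filter_eligible,
)
from telemon.synthetic_data import default_config, generate_cohort

settings.register_profile(
    "fixed", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("fixed")

# day codes for hand-built tables: (pre, call, post, vitals)
# p: transmitted before deadline, in range     o: before deadline, out of range
# c: call-rescued, in range                    r: call-rescued, out of range
# n: no transmission, call attempted           m: no transmission, no call
_DAY_CODES = {
    "p": (1, 0, 1, (120.0, 80.0, 70.0)),
    "o": (1, 0, 1, (170.0, 80.0, 70.0)),
    "c": (0, 1, 1, (120.0, 80.0, 70.0)),
    "r": (0, 1, 1, (170.0, 80.0, 70.0)),
    "n": (0, 1, 0, None),
    "m": (0, 0, 0, None),
}


def table_from_codes(
    codes_by_patient: dict[str, str],
    start: str = "2020-01-06",  # a Monday
    analysis_days: int | None = None,
    washout_days: int = 0,
) -> ObservationTable:
    """Build an ObservationTable from per-patient day-code strings."""
    rows = []
    start_ts = pd.Timestamp(start)
    for pid, codes in codes_by_patient.items():
        for day, code in enumerate(codes, start=1):
            pre, call, post, vit = _DAY_CODES[code]
            sbp, dbp, pulse = vit if vit else (np.nan, np.nan, np.nan)
            rows.append(
                {
                    "patient_id": pid,
                    "date": start_ts + pd.Timedelta(days=day - 1),
                    "study_day": day,
                    "transmitted_pre": bool(pre),
                    "call_attempted": bool(call),
                    "transmitted_post": bool(post),
                    "sbp": sbp,
                    "dbp": dbp,
                    "pulse": pulse,
                }
            )
    df = pd.DataFrame(rows)[["patient_id", "date", "study_day"] + DAILY_COLUMNS[2:]]
    df = df.sort_values(["patient_id", "study_day"], kind="mergesort").reset_index(drop=True)
    return ObservationTable(df, washout_days=washout_days, analysis_days=analysis_days)


def patients_frame(patient_ids, **overrides) -> pd.DataFrame:
    """Patient table with default alert ranges for the given ids."""
    base = {
        "age": 72,
        "sex": "female",
        "region": "McAllen",
        "urbanicity": "urban",
        "sbp_low": 90.0,
        "sbp_high": 160.0,
        "dbp_low": 60.0,
        "dbp_high": 90.0,
        "pulse_low": 60.0,
        "pulse_high": 120.0,
        "enrollment_date": pd.Timestamp("2020-01-06"),
    }
    base.update(overrides)
    return pd.DataFrame([{"patient_id": pid, **base} for pid in patient_ids])


def scaled_config(
    seed: int,
    n_adherent: int = 60,
    n_nonadherent: int = 40,
    n_short: int = 0,
    n_never: int = 0,
):
    """Default study configuration scaled down to a quick test size."""
    cfg = default_config(seed=seed)
    cfg = dataclasses.replace(
        cfg, n_short_records=n_short, n_never_transmitting=n_never
    )
    cfg.adherent = dataclasses.replace(cfg.adherent, n_patients=n_adherent)
    cfg.nonadherent = dataclasses.replace(cfg.nonadherent, n_patients=n_nonadherent)
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    """(patients, raw table, truth) for a 60+40-patient default-dynamics run."""
    cfg = scaled_config(seed=424242, n_short=8, n_never=6)
    patients, table, truth = generate_cohort(cfg, with_truth=True)
    return patients, table, truth, cfg


@pytest.fixture(scope="session")
def small_trimmed(small_cohort):
    """Classified, washout-trimmed analysis table + cohort labels + truth."""
    patients, table, truth, cfg = small_cohort
    trimmed, _ = filter_eligible(table, min_days=cfg.washout_days + cfg.analysis_days)
    trimmed = apply_washout(trimmed, cfg.washout_days, cfg.analysis_days)
    trimmed = classify_events(trimmed, patients)
    cohorts = classify_cohorts(trimmed)
    return patients, trimmed, cohorts, truth
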