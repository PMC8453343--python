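"""Month-1 vs month-5 blood-pressure change analysis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from telemon.bp_outcomes import (
    bp_change_analysis,
    monthly_bp_means,
    uncontrolled_subgroup,
)
from telemon.io_model import apply_washout, classify_events
from telemon.synthetic_data import UncontrolledStratum, generate_cohort

from conftest import patients_frame, scaled_config, table_from_codes


def means_frame(rows):
    """rows: (patient_id, month, sbp_mean, dbp_mean)"""
    return pd.DataFrame(
        [
            {"patient_id": p, "month": m, "sbp_mean": s, "dbp_mean": d, "n_readings": 10}
            for p, m, s, d in rows
        ]
    )


def cohort_series(mapping):
    s = pd.Series(mapping, name="cohort")
    s.index.name = "patient_id"
    return s


class TestMonthlyMeans:
    def test_hand_means_per_month(self):
        t = table_from_codes({"A": "pp" + "m" * 28 + "p" * 30}, analysis_days=60)
        # give month-1 days distinct readings 120 and 140 -> mean 130
        t.data.loc[t.data["study_day"] == 2, "sbp"] = 140.0
        out = monthly_bp_means(t)
        m1 = out[(out["patient_id"] == "A") & (out["month"] == 1)].iloc[0]
        assert m1["sbp_mean"] == 130.0 and m1["n_readings"] == 2

    def test_constant_reading_constant_means(self):
        t = table_from_codes({"A": "p" * 150}, analysis_days=150)
        out = monthly_bp_means(t)
        assert (out["sbp_mean"] == 120.0).all() and len(out) == 5

    def test_empty_month_yields_no_record(self):
        t = table_from_codes({"A": "p" * 120 + "m" * 30}, analysis_days=150)
        out = monthly_bp_means(t)
        assert set(out["month"]) == {1, 2, 3, 4}


class TestChangeAnalysis:
    def test_hand_mean_change(self):
        means = means_frame(
            [("A", 1, 132, 80), ("A", 5, 130, 80), ("B", 1, 140, 82), ("B", 5, 136, 82)]
        )
        cohorts = cohort_series({"A": "adherent", "B": "adherent"})
        res = bp_change_analysis(means, cohorts, "sbp").results["adherent"]
        assert res.mean_change == pytest.approx(3.0)  # changes {+2, +4}
        assert res.n_included == 2

    def test_zero_changes_degenerate_p(self):
        means = means_frame([("A", 1, 130, 80), ("A", 5, 130, 80), ("B", 1, 140, 82), ("B", 5, 140, 82)])
        cohorts = cohort_series({"A": "adherent", "B": "adherent"})
        res = bp_change_analysis(means, cohorts, "sbp").results["adherent"]
        assert res.mean_change == 0.0 and res.p_paired is None

    def test_missing_month_excludes_only_that_patient(self):
        means = means_frame(
            [("A", 1, 132, 80), ("A", 5, 130, 80), ("B", 1, 140, 82),
             ("C", 1, 150, 84), ("C", 5, 145, 84)]
        )
        cohorts = cohort_series({"A": "adherent", "B": "adherent", "C": "adherent"})
        res = bp_change_analysis(means, cohorts, "sbp").results["adherent"]
        assert res.n_included == 2 and res.n_excluded_missing_month == 1
        # linearity: mean change equals difference of means over included set
        assert res.mean_change == pytest.approx(((132 + 150) - (130 + 145)) / 2)

    def test_fewer_than_two_patients_errors(self):
        means = means_frame([("A", 1, 132, 80), ("A", 5, 130, 80)])
        cohorts = cohort_series({"A": "adherent"})
        with pytest.raises(ValueError, match="fewer than 2"):
            bp_change_analysis(means, cohorts, "sbp")

    def test_between_cohort_p_present(self):
        rng = np.random.default_rng(0)
        rows = []
        labels = {}
        for i in range(30):
            pid = f"A{i}"
            rows += [(pid, 1, 133 + rng.normal(), 80), (pid, 5, 130 + rng.normal(), 80)]
            labels[pid] = "adherent"
        for i in range(30):
            pid = f"N{i}"
            rows += [(pid, 1, 137 + rng.normal(), 82), (pid, 5, 137 + rng.normal(), 82)]
            labels[pid] = "nonadherent"
        cmp = bp_change_analysis(means_frame(rows), cohort_series(labels), "sbp")
        assert cmp.p_between is not None and cmp.p_between < 0.05


class TestUncontrolledSubgroup:
    def test_strict_boundary(self):
        means = means_frame(
            [("A", 1, 141, 91), ("A", 5, 130, 84),
             ("B", 1, 140, 90), ("B", 5, 130, 84),
             ("C", 1, 145, 95), ("C", 5, 132, 86)]
        )
        cohorts = cohort_series({p: "adherent" for p in "ABC"})
        sub = uncontrolled_subgroup(means, cohorts, "sbp")
        # 141/91 included (strict >), 140/90 excluded
        assert sub.n_subgroup == 2
        assert sub.results["adherent"].n_included == 2

    def test_and_vs_or_combination(self):
        means = means_frame([("A", 1, 141, 85), ("A", 5, 130, 80), ("B", 1, 142, 92), ("B", 5, 130, 80)])
        cohorts = cohort_series({"A": "adherent", "B": "adherent"})
        assert uncontrolled_subgroup(means, cohorts).n_subgroup == 1
        assert uncontrolled_subgroup(means, cohorts, combine="or").n_subgroup == 2

    def test_empty_subgroup_explicit_result(self):
        means = means_frame([("A", 1, 120, 70), ("A", 5, 118, 70), ("B", 1, 125, 72), ("B", 5, 125, 72)])
        cohorts = cohort_series({"A": "adherent", "B": "adherent"})
        sub = uncontrolled_subgroup(means, cohorts)
        assert sub.n_subgroup == 0 and sub.results == {}


class TestParameterRecovery:
    def test_configured_sbp_improvement_recovered(self):
        cfg = scaled_config(seed=31, n_adherent=200, n_nonadherent=0)
        cfg.adherent = dataclasses.replace(cfg.adherent, uncontrolled=UncontrolledStratum(0.0))
        patients, table = generate_cohort(cfg)
        trimmed = apply_washout(table, cfg.washout_days, cfg.analysis_days)
        trimmed = classify_events(trimmed, patients)
        means = monthly_bp_means(trimmed)
        cohorts = pd.Series(
            "adherent", index=pd.Index(patients["patient_id"], name="patient_id"), name="cohort"
        )
        res = bp_change_analysis(means, cohorts, "sbp").results["adherent"]
        # configured improvement 2.2 mm Hg, change SD 9.5, n=200
        assert res.mean_change == pytest.approx(2.2, abs=2.0)
        assert res.sd_change == pytest.approx(9.5, abs=2.0)

    def test_uncontrolled_stratum_improvement_recovered(self):
        # subgroup of ~120 patients; per-cohort change SD 10 -> SE ~0.95,
        # so a 3-sigma band around the configured 14.8 mm Hg is ~3
        cfg = scaled_config(seed=37, n_adherent=300, n_nonadherent=0)
        cfg.adherent = dataclasses.replace(
            cfg.adherent, uncontrolled=dataclasses.replace(
                cfg.adherent.uncontrolled, fraction=0.4, sbp_improvement=14.8
            )
        )
        patients, table = generate_cohort(cfg)
        trimmed = apply_washout(table, cfg.washout_days, cfg.analysis_days)
        trimmed = classify_events(trimmed, patients)
        means = monthly_bp_means(trimmed)
        cohorts = pd.Series(
            "adherent", index=pd.Index(patients["patient_id"], name="patient_id"), name="cohort"
        )
        sub = uncontrolled_subgroup(means, cohorts, "sbp")
        assert sub.n_subgroup >= 90
        assert sub.results["adherent"].mean_change == pytest.approx(14.8, abs=3.0)
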