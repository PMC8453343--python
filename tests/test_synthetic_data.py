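"""Generator: configuration, reproducibility, and recovery of the configured
statistical structure."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from telemon.adherence_metrics import transmission_rate, monthly_rates
from telemon.io_model import apply_washout, classify_events, write_daily_records
from telemon.synthetic_data import (
    ADHERENT_TRANSITIONS_PCT,
    ConfigError,
    SimulationConfig,
    UncontrolledStratum,
    default_config,
    generate_cohort,
    load_config,
    save_config,
)
from telemon.transition_analysis import (
    estimate_transition_matrix,
    event_sequences,
    stationary_distribution,
)

from conftest import scaled_config


class TestDefaultConfig:
    def test_rows_are_renormalized_published_percentages(self):
        cfg = default_config()
        P = np.asarray(cfg.adherent.transition_matrix)
        raw = np.asarray(ADHERENT_TRANSITIONS_PCT) / 100.0
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(P, raw / raw.sum(axis=1, keepdims=True), atol=1e-12)

    def test_pre_given_transmit_is_ratio_of_printed_rates(self):
        cfg = default_config()
        assert cfg.adherent.p_pre_given_transmit == pytest.approx(0.749 / 0.913)
        assert cfg.nonadherent.p_pre_given_transmit == pytest.approx(0.390 / 0.580)

    def test_cohort_sizes_and_funnel(self):
        cfg = default_config()
        assert (cfg.adherent.n_patients, cfg.nonadherent.n_patients) == (475, 348)
        total = (
            cfg.adherent.n_patients
            + cfg.nonadherent.n_patients
            + cfg.n_short_records
            + cfg.n_never_transmitting
        )
        assert total == 2093

    def test_initial_distribution_defaults_to_stationary(self):
        cfg = default_config()
        P = np.asarray(cfg.adherent.transition_matrix)
        pi = cfg.adherent.initial()
        np.testing.assert_allclose(pi @ P, pi, atol=1e-12)
        # independent oracle: dominant left eigenvector
        w, v = np.linalg.eig(P.T)
        lead = np.real(v[:, np.argmax(np.real(w))])
        np.testing.assert_allclose(pi, lead / lead.sum(), atol=1e-9)

    def test_validation_rejects_bad_rows(self):
        cfg = default_config()
        cfg.adherent = dataclasses.replace(
            cfg.adherent, transition_matrix=((0.5, 0.2, 0.2), (0.1, 0.8, 0.1), (0, 0, 1.0))
        )
        with pytest.raises(ConfigError, match="sum to 1"):
            cfg.validate()

    def test_validation_rejects_short_raw_window(self):
        cfg = default_config()
        cfg.n_days_raw = 100
        with pytest.raises(ConfigError, match="washout"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config(seed=9)
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        back = load_config(path)
        assert _plain_eq(back.to_dict(), cfg.to_dict())


def _plain_eq(a, b) -> bool:
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(_plain_eq(a[k], b[k]) for k in a)
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return len(a) == len(b) and all(_plain_eq(x, y) for x, y in zip(a, b))
    if isinstance(a, float) or isinstance(b, float):
        return float(a) == pytest.approx(float(b), abs=1e-12)
    return a == b


class TestReproducibility:
    def test_same_seed_byte_identical_csv(self):
        cfg = scaled_config(seed=5, n_adherent=12, n_nonadherent=8)
        bufs = []
        for _ in range(2):
            _, table = generate_cohort(dataclasses.replace(cfg))
            buf = io.StringIO()
            write_daily_records(table, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_seed_changes_output(self):
        cfg = scaled_config(seed=5, n_adherent=12, n_nonadherent=8)
        _, t1 = generate_cohort(cfg)
        _, t2 = generate_cohort(dataclasses.replace(cfg, seed=6))
        assert not t1.data.equals(t2.data)


class TestGeneratedStructure:
    def test_vitals_match_event_labels(self, small_trimmed):
        # classify_event applied to the generated vitals reproduces the
        # generator's internal labels exactly
        patients, trimmed, _, truth = small_trimmed
        raw_day = trimmed.data["study_day"] + trimmed.washout_days
        merged = trimmed.data.assign(raw_day=raw_day).merge(
            truth.daily, left_on=["patient_id", "raw_day"],
            right_on=["patient_id", "study_day"], suffixes=("", "_truth"),
        )
        assert len(merged) == len(trimmed.data)
        assert (merged["event"].astype(str) == merged["event_truth"].astype(str)).all()

    def test_latent_labels_complete_and_consistent(self, small_cohort):
        _, _, truth, _ = small_cohort
        d = truth.daily
        assert (d.loc[d["event"] != "NT", "event"].astype(str)
                == d.loc[d["event"] != "NT", "latent_event"].astype(str)).all()
        assert set(d.loc[d["event"] == "NT", "latent_event"].astype(str)) <= {"ORT", "IRT"}

    def test_transition_matrix_recovery(self):
        # moderate-size adherent arm: re-estimated matrix close to configured
        cfg = scaled_config(seed=77, n_adherent=200, n_nonadherent=0)
        patients, table = generate_cohort(cfg)
        trimmed = apply_washout(table, cfg.washout_days, cfg.analysis_days)
        trimmed = classify_events(trimmed, patients)
        m = estimate_transition_matrix(event_sequences(trimmed))
        configured = 100.0 * np.asarray(cfg.adherent.transition_matrix)
        err = np.abs(m.probs.to_numpy() - configured).max()
        assert err < 3.0  # worst-cell Monte-Carlo error at 200 x 150

    def test_pre_and_post_rates_recovered(self):
        cfg = scaled_config(seed=11, n_adherent=150, n_nonadherent=0)
        patients, table = generate_cohort(cfg)
        trimmed = apply_washout(table, cfg.washout_days, cfg.analysis_days)
        pi = stationary_distribution(np.asarray(cfg.adherent.transition_matrix))
        expected_post = 100.0 * (1.0 - pi[0])
        expected_pre = expected_post * cfg.adherent.p_pre_given_transmit
        assert transmission_rate(trimmed, "post") == pytest.approx(expected_post, abs=1.5)
        assert transmission_rate(trimmed, "pre") == pytest.approx(expected_pre, abs=1.5)

    def test_monthly_decline_recovered(self):
        # an additive decline of 1.9 points from analysis month 1 to month 5
        cfg = scaled_config(seed=13, n_adherent=400, n_nonadherent=0)
        cfg.adherent = dataclasses.replace(cfg.adherent, monthly_decline=0.019 / 4.0)
        patients, table = generate_cohort(cfg)
        trimmed = apply_washout(table, cfg.washout_days, cfg.analysis_days)
        mr = monthly_rates(trimmed)
        assert mr.post_drop == pytest.approx(1.9, abs=1.3)

    def test_homogeneous_default_has_flat_months(self):
        cfg = scaled_config(seed=17, n_adherent=300, n_nonadherent=0)
        patients, table = generate_cohort(cfg)
        trimmed = apply_washout(table, cfg.washout_days, cfg.analysis_days)
        mr = monthly_rates(trimmed)
        assert abs(mr.post_drop) < 1.5

    def test_weekday_nt_modulation_lowers_sunday(self):
        cfg = scaled_config(seed=19, n_adherent=200, n_nonadherent=0)
        # Monday-first factors: boost NT probability on Sunday
        cfg.weekday_nt_modulation = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 2.5)
        patients, table = generate_cohort(cfg)
        trimmed = apply_washout(table, cfg.washout_days, cfg.analysis_days)
        df = trimmed.data
        wd = pd.to_datetime(df["date"]).dt.weekday
        sunday = 100.0 * df.loc[wd == 6, "transmitted_post"].mean()
        weekdays = 100.0 * df.loc[wd < 5, "transmitted_post"].mean()
        assert sunday < weekdays - 2.0

    def test_personalized_range_fraction(self):
        cfg = scaled_config(seed=23, n_adherent=400, n_nonadherent=0)
        cfg.adherent = dataclasses.replace(cfg.adherent, uncontrolled=UncontrolledStratum(0.0))
        patients, _ = generate_cohort(cfg)
        pers = (patients["sbp_low"] != 90.0) | (patients["sbp_high"] != 160.0)
        assert pers.mean() == pytest.approx(0.112, abs=0.05)
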