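"""Transition-matrix estimation, conditional statistics, gaps, hitting times."""

import numpy as np
import pytest

from telemon.io_model import EVENTS
from telemon.stats_util import round_half_away
from telemon.transition_analysis import (
    GapSummary,
    TransitionMatrix,
    analytic_hitting_time,
    conditional_adherence,
    conditional_in_range,
    estimate_transition_matrix,
    event_sequences,
    mean_gap_to_in_range,
    stationary_distribution,
)

# published next-day rows used as worked-example inputs
ADHERENT_ROWS = {"NT": (32.9, 29.3, 37.8), "ORT": (5.6, 41.6, 52.7), "IRT": (6.3, 32.0, 61.7)}
NONADHERENT_ROWS = {"NT": (61.7, 18.5, 19.8), "ORT": (28.9, 34.8, 36.3), "IRT": (29.6, 28.0, 42.5)}


def seqs(*strings):
    decode = {"N": "NT", "O": "ORT", "I": "IRT"}
    return {
        f"P{i}": np.array([decode[c] for c in s], dtype=object)
        for i, s in enumerate(strings)
    }


class TestEstimate:
    def test_all_irt_sequence(self):
        m = estimate_transition_matrix(seqs("III"))
        assert m.probs.loc["IRT", "IRT"] == 100.0
        assert m.n_pairs == 2

    def test_hand_counted_pairs(self):
        m = estimate_transition_matrix(seqs("NOIN"))
        assert m.counts.loc["NT", "ORT"] == 1
        assert m.counts.loc["ORT", "IRT"] == 1
        assert m.counts.loc["IRT", "NT"] == 1
        for frm, to in (("NT", "ORT"), ("ORT", "IRT"), ("IRT", "NT")):
            assert m.probs.loc[frm, to] == 100.0

    def test_no_pair_spans_two_patients(self):
        m = estimate_transition_matrix(seqs("II", "NN"))
        assert m.counts.loc["IRT", "NT"] == 0
        assert m.n_pairs == 2

    def test_unobserved_from_state_row_is_absent(self):
        m = estimate_transition_matrix(seqs("II"))
        assert m.probs.loc["NT"].isna().all()
        with pytest.raises(ValueError, match="absent"):
            m.row("NT")

    def test_row_counts_sum_to_pairs(self, small_trimmed):
        _, trimmed, _, _ = small_trimmed
        sequences = event_sequences(trimmed)
        m = estimate_transition_matrix(sequences)
        expected_pairs = sum(len(s) - 1 for s in sequences.values())
        assert m.counts.to_numpy().sum() == expected_pairs
        row_sums = m.probs.sum(axis=1)
        np.testing.assert_allclose(row_sums, 100.0, atol=1e-9)

    def test_sequences_match_generator_labels(self, small_trimmed):
        patients, trimmed, _, truth = small_trimmed
        sequences = event_sequences(trimmed)
        td = truth.daily.set_index(["patient_id", "study_day"])["event"]
        pid = next(iter(sequences))
        expected = td.loc[pid].sort_index().iloc[trimmed.washout_days:
                                                 trimmed.washout_days + 150]
        assert list(sequences[pid]) == [str(e) for e in expected]


class TestConditionals:
    def test_published_adherent_values(self):
        m = TransitionMatrix.from_percent_rows(ADHERENT_ROWS)
        assert round_half_away(conditional_adherence(m, "NT")) == 67.1
        assert round_half_away(conditional_in_range(m, "NT")) == 56.3
        assert round_half_away(conditional_in_range(m, "IRT")) == 65.8

    def test_published_nonadherent_values(self):
        m = TransitionMatrix.from_percent_rows(NONADHERENT_ROWS)
        assert round_half_away(conditional_adherence(m, "NT")) == 38.3
        assert round_half_away(conditional_in_range(m, "NT")) == 51.7  # 19.8/38.3

    def test_degenerate_rows(self):
        m = TransitionMatrix.from_percent_rows({"NT": (0.0, 50.0, 50.0)})
        assert conditional_adherence(m, "NT") == 100.0
        assert conditional_in_range(m, "NT") == 50.0
        m2 = TransitionMatrix.from_percent_rows({"NT": (100.0, 0.0, 0.0)})
        with pytest.raises(ValueError, match="no transmissions"):
            conditional_in_range(m2, "NT")

    def test_adherence_equals_transmit_mass(self):
        m = TransitionMatrix.from_percent_rows(ADHERENT_ROWS)
        for ev in EVENTS:
            r = m.row(ev)
            assert conditional_adherence(m, ev) == pytest.approx(
                r["ORT"] + r["IRT"], abs=0.15  # published rows carry rounding
            )


class TestGaps:
    def test_hand_examples(self):
        assert mean_gap_to_in_range(seqs("OI")).mean_days == 1.0
        assert mean_gap_to_in_range(seqs("ONNI")).mean_days == 3.0
        pooled = mean_gap_to_in_range(seqs("OI", "ONI"))
        assert pooled == GapSummary(1.5, 2, 0)

    def test_censoring_reported(self):
        g = mean_gap_to_in_range(seqs("OI", "ON"))
        assert g.mean_days == 1.0 and g.n_gaps == 1 and g.n_censored == 1

    def test_no_eligible_occurrence_raises(self):
        with pytest.raises(ValueError):
            mean_gap_to_in_range(seqs("ONN"))


class TestHittingTime:
    def test_certain_one_step(self):
        m = TransitionMatrix.from_percent_rows(
            {"NT": (100.0, 0, 0), "ORT": (0, 0, 100.0), "IRT": (0, 0, 100.0)}
        )
        assert analytic_hitting_time(m, "ORT") == pytest.approx(1.0)

    def test_unreachable_target_raises(self):
        m = TransitionMatrix.from_percent_rows(
            {"NT": (100.0, 0, 0), "ORT": (50.0, 50.0, 0), "IRT": (0, 0, 100.0)}
        )
        with pytest.raises(ValueError, match="unreachable"):
            analytic_hitting_time(m, "NT", "IRT")

    def test_published_matrices_hand_solved_values(self):
        # two-unknown linear systems solved by hand for the published rows
        m_a = TransitionMatrix.from_percent_rows(ADHERENT_ROWS)
        m_n = TransitionMatrix.from_percent_rows(NONADHERENT_ROWS)
        assert analytic_hitting_time(m_a, "ORT") == pytest.approx(1.938, abs=0.01)
        assert analytic_hitting_time(m_n, "ORT") == pytest.approx(3.424, abs=0.01)

    def test_agrees_with_long_chain_simulation(self):
        m = TransitionMatrix.from_percent_rows(ADHERENT_ROWS)
        P = m.fractions()
        rng = np.random.default_rng(12345)
        n_steps = 200_000
        cum = np.cumsum(P, axis=1)
        states = np.empty(n_steps, dtype=np.int64)
        states[0] = 1
        u = rng.random(n_steps)
        for t in range(1, n_steps):
            states[t] = np.searchsorted(cum[states[t - 1]], u[t])
        chain = {"chain": np.array(list(EVENTS), dtype=object)[states]}
        empirical = mean_gap_to_in_range(chain, from_event="ORT").mean_days
        analytic = analytic_hitting_time(m, "ORT")
        assert empirical == pytest.approx(analytic, rel=0.02)


def test_stationary_distribution_is_left_fixed_point():
    P = TransitionMatrix.from_percent_rows(NONADHERENT_ROWS).fractions()
    pi = stationary_distribution(P)
    np.testing.assert_allclose(pi @ P, pi, atol=1e-12)
    assert pi.sum() == pytest.approx(1.0)
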