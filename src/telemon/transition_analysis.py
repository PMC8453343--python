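"""Next-day transition structure of daily transmission events.

Treating each patient's 150-day event sequence (NT / ORT / IRT) as a
categorical time series, this module estimates the pooled first-order
transition matrix, derives the conditional adherence and conditional
in-range statistics implied by a row of that matrix, measures empirical
gaps to the next in-range transmission, and solves the analytic expected
first-passage (hitting) time of the corresponding three-state Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import EVENTS, IRT, NT, ORT, ObservationTable

__all__ = [
    "TransitionMatrix",
    "GapSummary",
    "event_sequences",
    "estimate_transition_matrix",
    "conditional_adherence",
    "conditional_in_range",
    "mean_gap_to_in_range",
    "analytic_hitting_time",
    "stationary_distribution",
]

_CODE = {e: i for i, e in enumerate(EVENTS)}


@dataclass
class TransitionMatrix:
    """Pooled next-day transition matrix over the three transmission events.

    ``probs`` holds row percentages (each observed row sums to 100 up to
    float error); rows never observed are all-NaN rather than zero-filled.
    ``counts``/``n_pairs`` are ``None`` when the matrix was built directly
    from published row percentages rather than estimated from sequences.
    """

    probs: pd.DataFrame
    counts: pd.DataFrame | None = None
    n_pairs: int | None = None

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "TransitionMatrix":
        counts = np.asarray(counts)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise ValueError("counts must be a nonnegative 3x3 array")
        cdf = pd.DataFrame(counts, index=list(EVENTS), columns=list(EVENTS), dtype=int)
        row_totals = cdf.sum(axis=1)
        probs = 100.0 * cdf.div(row_totals.where(row_totals > 0), axis=0)
        return cls(probs=probs, counts=cdf, n_pairs=int(counts.sum()))

    @classmethod
    def from_percent_rows(cls, rows) -> "TransitionMatrix":
        """Build from row percentages, e.g. a published next-day table.

        ``rows`` maps from-event to a (NT, ORT, IRT) percent triple; from-events
        not supplied become absent (NaN) rows.
        """
        probs = pd.DataFrame(np.nan, index=list(EVENTS), columns=list(EVENTS))
        for ev, triple in dict(rows).items():
            if ev not in _CODE:
                raise ValueError(f"unknown event {ev!r}")
            probs.loc[ev] = np.asarray(triple, dtype=float)
        return cls(probs=probs)

    def row(self, from_event: str) -> pd.Series:
        if from_event not in _CODE:
            raise ValueError(f"unknown event {from_event!r}")
        r = self.probs.loc[from_event]
        if r.isna().any():
            raise ValueError(f"transition row for {from_event} is absent (never observed)")
        return r

    def fractions(self) -> np.ndarray:
        """Row-renormalized transition fractions (rows summing exactly to 1).

        Published percent rows may sum to 99.9 or 100.1 after rounding; the
        renormalization makes them proper distributions for chain arithmetic.
        """
        p = self.probs.to_numpy(dtype=float)
        if np.isnan(p).any():
            raise ValueError("cannot form a complete chain: some rows are absent")
        return p / p.sum(axis=1, keepdims=True)


def event_sequences(table: ObservationTable) -> dict[str, np.ndarray]:
    """Ordered per-patient event sequences from a classified table."""
    if "event" not in table.data.columns:
        raise ValueError("table has no 'event' column; run classify_events first")
    df = table.data.sort_values(["patient_id", "study_day"], kind="mergesort")
    return {
        pid: grp["event"].to_numpy(dtype=object)
        for pid, grp in df.groupby("patient_id", sort=True)
    }


def estimate_transition_matrix(
    sequences: dict[str, np.ndarray], patient_ids=None
) -> TransitionMatrix:
    """Pool within-patient consecutive-day pairs and row-normalize.

    No pair spans two patients.  From-states never observed yield an absent
    (NaN) probability row, not a zero-filled one.
    """
    if patient_ids is not None:
        wanted = set(patient_ids)
        sequences = {p: s for p, s in sequences.items() if p in wanted}
    counts = np.zeros(9, dtype=np.int64)
    for seq in sequences.values():
        if len(seq) < 2:
            continue
        codes = np.fromiter((_CODE[e] for e in seq), dtype=np.int64, count=len(seq))
        counts += np.bincount(codes[:-1] * 3 + codes[1:], minlength=9)
    counts = counts.reshape(3, 3)
    if counts.sum() == 0:
        raise ValueError("no consecutive-day pairs in scope")
    return TransitionMatrix.from_counts(counts)


def conditional_adherence(m: TransitionMatrix, from_event: str) -> float:
    """Percent of days following a ``from_event`` day that saw a transmission:
    100 - P(NT | from)."""
    return 100.0 - float(m.row(from_event)[NT])


def conditional_in_range(m: TransitionMatrix, from_event: str) -> float:
    """Percent of next-day transmissions that were in range, conditional on
    the prior day's event: 100 * P(IRT|from) / (P(ORT|from) + P(IRT|from))."""
    r = m.row(from_event)
    denom = float(r[ORT] + r[IRT])
    if denom <= 0:
        raise ValueError(f"no transmissions ever follow {from_event}")
    return 100.0 * float(r[IRT]) / denom


@dataclass(frozen=True)
class GapSummary:
    """Mean days from a from-event day to the patient's next in-range
    transmission, with the number of window-censored from-days excluded."""

    mean_days: float
    n_gaps: int
    n_censored: int


def mean_gap_to_in_range(sequences: dict[str, np.ndarray], from_event: str = ORT) -> GapSummary:
    """Empirical mean gap (in days) from each ``from_event`` day to the next
    IRT day within the same patient's window.

    From-days with no subsequent IRT before the window ends are censored:
    excluded from the mean but counted in the summary.
    """
    gaps: list[np.ndarray] = []
    n_censored = 0
    for seq in sequences.values():
        codes = np.fromiter((_CODE[e] for e in seq), dtype=np.int64, count=len(seq))
        from_pos = np.flatnonzero(codes == _CODE[from_event])
        if from_pos.size == 0:
            continue
        irt_pos = np.flatnonzero(codes == _CODE[IRT])
        nxt = np.searchsorted(irt_pos, from_pos, side="right")
        ok = nxt < irt_pos.size
        gaps.append(irt_pos[nxt[ok]] - from_pos[ok])
        n_censored += int((~ok).sum())
    if not gaps or sum(g.size for g in gaps) == 0:
        raise ValueError(f"no {from_event} day is followed by an in-range transmission")
    pooled = np.concatenate(gaps)
    return GapSummary(float(pooled.mean()), int(pooled.size), n_censored)


def _reachable(P: np.ndarray, start: int) -> set[int]:
    seen = {start}
    frontier = [start]
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(P[i] > 0):
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    return seen


def analytic_hitting_time(m: TransitionMatrix, from_event: str, to_event: str = IRT) -> float:
    """Expected first-passage time (days) from one event state to another.

    Solves the standard linear system h = 1 + Q h on the states other than the
    target, where Q is the chain restricted to those states.
    """
    P = m.fractions()
    i, j = _CODE[from_event], _CODE[to_event]
    if j not in _reachable(P, i) or (i == j and P[i, j] < 1.0 and j not in
                                     set().union(*(_reachable(P, k) for k in range(3) if P[i, k] > 0))):
        raise ValueError(f"{to_event} unreachable from {from_event}")
    # restrict the system to the non-target states reachable from the start;
    # the reachable set is closed, so the system is self-contained
    reach = _reachable(P, i)
    S = sorted(s for s in reach if s != j)
    for s in S:
        if j not in _reachable(P, s):
            raise ValueError(
                f"expected hitting time from {from_event} is infinite: "
                f"{EVENTS[s]} cannot reach {to_event}"
            )
    if S:
        Q = P[np.ix_(S, S)]
        h = np.linalg.solve(np.eye(len(S)) - Q, np.ones(len(S)))
        h_map = dict(zip(S, h))
    else:
        h_map = {}
    if i == j:
        # a same-state query means "next occurrence": first passage after one step
        return float(1.0 + sum(P[i, k] * h_map.get(k, 0.0) for k in range(3) if k != j))
    return float(h_map[i])


def stationary_distribution(P) -> np.ndarray:
    """Stationary distribution of a 3x3 row-stochastic matrix (linear solve)."""
    P = np.asarray(P, dtype=float)
    if P.shape != (3, 3):
        raise ValueError("P must be 3x3")
    A = np.vstack([(P.T - np.eye(3))[:2], np.ones(3)])
    pi = np.linalg.solve(A, np.array([0.0, 0.0, 1.0]))
    if (pi < -1e-9).any():
        raise ValueError("chain has no valid stationary distribution")
    return np.clip(pi, 0.0, None) / pi.sum()
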