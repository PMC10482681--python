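"""Summaries of decoded state sequences and arena-trajectory metrics.

State-sequence metrics (occupancy, bouts, transition counts and
transition-event times) operate on semantic 1/2/3 sequences; the transition
event convention places each event at the start time of the first bin of the
NEW state, so that photometry windows centre on state entry.

Trajectory metrics cover the two-chamber real-time place preference (RTPP)
assay — percentage of session time spent on the stimulated side, and change
in preference relative to a laser-off baseline — and the open-field test,
whose centre zone is the concentric square holding a configurable fraction
(default 40%) of the arena AREA, i.e. side length L*sqrt(0.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import StateSequence

__all__ = [
    "SEMANTIC_STATES",
    "OccupancySummary",
    "TransitionCounts",
    "TransitionEventSeries",
    "RTPPSession",
    "ArenaSpec",
    "occupancy_fractions",
    "transition_counts",
    "state_transition_events",
    "bout_table",
    "rtpp_time_fraction",
    "rtpp_preference_change",
    "open_field_center_metrics",
]

SEMANTIC_STATES = (1, 2, 3)


def _require_semantic(states: StateSequence) -> np.ndarray:
    if not states.semantic:
        raise ValueError("sequence carries raw indices; relabel to semantic first")
    if len(states) == 0:
        raise ValueError("empty state sequence")
    return states.states


@dataclass
class OccupancySummary:
    """Fraction of bins and total duration (s) per semantic state."""

    fractions: dict[int, float]
    durations_s: dict[int, float]


@dataclass
class TransitionCounts:
    """Off-diagonal i->j change counts plus per-source outbound totals."""

    counts: np.ndarray  # (3, 3), indexed [from-1, to-1], zero diagonal
    outbound: dict[int, int]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, i: int, j: int) -> int:
        return int(self.counts[i - 1, j - 1])


@dataclass
class TransitionEventSeries:
    """Times (s) of i->j state-entry events for one (from, to) pair."""

    times_s: np.ndarray
    from_state: int
    to_state: int

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class RTPPSession:
    """Two-chamber trajectory with a stimulated side and divider position."""

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    stim_side: str  # "left" | "right"
    divider_x: float = 30.0
    arena_w: float = 60.0
    arena_h: float = 25.0
    phase: str = "stimulated"
    temperature_condition: str = ""

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if not (len(self.t_s) == len(self.x_cm) == len(self.y_cm)):
            raise ValueError("t, x, y must share a length")
        if len(self.t_s) > 1 and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.stim_side not in ("left", "right"):
            raise ValueError("stim_side must be 'left' or 'right'")


@dataclass
class ArenaSpec:
    """Square open-field arena with a centre zone given as an AREA fraction."""

    width_cm: float = 60.0
    height_cm: float = 60.0
    center_area_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.center_area_fraction < 1:
            raise ValueError("center_area_fraction must be in (0, 1)")

    @property
    def center_side_cm(self) -> float:
        return self.width_cm * np.sqrt(self.center_area_fraction)


def occupancy_fractions(states: StateSequence) -> OccupancySummary:
    """Per-state time fraction; durations = fraction * T * bin_s."""
    s = _require_semantic(states)
    T = len(s)
    fractions = {k: float(np.count_nonzero(s == k)) / T for k in SEMANTIC_STATES}
    durations = {k: fractions[k] * T * states.bin_s for k in SEMANTIC_STATES}
    return OccupancySummary(fractions=fractions, durations_s=durations)


def transition_counts(states: StateSequence) -> TransitionCounts:
    """Counts of observed state changes (i != j) between consecutive bins."""
    s = _require_semantic(states)
    if len(s) < 2:
        raise ValueError("need at least two bins to count transitions")
    counts = np.zeros((3, 3), dtype=np.int64)
    frm, to = s[:-1], s[1:]
    changed = frm != to
    np.add.at(counts, (frm[changed] - 1, to[changed] - 1), 1)
    outbound = {i: int(counts[i - 1].sum()) for i in SEMANTIC_STATES}
    return TransitionCounts(counts=counts, outbound=outbound)


def state_transition_events(
    states: StateSequence, from_state: int, to_state: int
) -> TransitionEventSeries:
    """Entry times of ``to_state`` bouts reached directly from ``from_state``.

    Event time = start time of the first bin of the new state.
    """
    if from_state == to_state:
        raise ValueError("from_state and to_state must differ")
    s = _require_semantic(states)
    hits = np.flatnonzero((s[:-1] == from_state) & (s[1:] == to_state))
    times = states.t0 + (hits + 1) * states.bin_s
    return TransitionEventSeries(
        times_s=times.astype(float), from_state=from_state, to_state=to_state
    )


def bout_table(states: StateSequence) -> pd.DataFrame:
    """Maximal constant runs as rows of (state, start_s, end_s, duration_s)."""
    s = _require_semantic(states)
    change = np.flatnonzero(np.diff(s) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(s)]))
    return pd.DataFrame(
        {
            "state": s[starts],
            "start_s": states.t0 + starts * states.bin_s,
            "end_s": states.t0 + ends * states.bin_s,
            "duration_s": (ends - starts) * states.bin_s,
        }
    )


def _dwell_weights(t: np.ndarray) -> np.ndarray:
    # forward differences; the final sample carries the session's median dwell
    dt = np.diff(t)
    return np.concatenate((dt, [float(np.median(dt))]))


def _on_stim_side(session: RTPPSession) -> np.ndarray:
    # samples exactly on the divider count toward the non-stimulated side
    if session.stim_side == "right":
        return session.x_cm > session.divider_x
    return session.x_cm < session.divider_x


def rtpp_time_fraction(session: RTPPSession) -> float:
    """Dwell-weighted percentage of session time on the stimulated side."""
    if len(session.t_s) < 2:
        raise ValueError("trajectory needs at least two samples")
    w = _dwell_weights(session.t_s)
    on = _on_stim_side(session)
    return float(100.0 * w[on].sum() / w.sum())


def rtpp_preference_change(stim_pct: float, baseline_pct: float) -> float:
    """Percent change in stimulated-side preference vs the laser-off baseline."""
    if baseline_pct == 0:
        raise ValueError("baseline preference of 0% leaves the change undefined")
    return 100.0 * (stim_pct - baseline_pct) / baseline_pct


def open_field_center_metrics(
    t_s: np.ndarray,
    x_cm: np.ndarray,
    y_cm: np.ndarray,
    arena: ArenaSpec | None = None,
) -> tuple[float, float]:
    """Centre-zone time fraction and in-zone path length for an open field.

    The zone is the concentric square containing ``center_area_fraction`` of
    the arena area.  Time fraction is dwell-weighted; distance sums segment
    lengths whose both endpoints lie in the zone.
    """
    arena = arena or ArenaSpec()
    if arena.width_cm != arena.height_cm:
        raise ValueError("centre-zone rule is defined for square arenas only")
    t = np.asarray(t_s, dtype=float)
    x = np.asarray(x_cm, dtype=float)
    y = np.asarray(y_cm, dtype=float)
    if len(t) < 2:
        raise ValueError("trajectory needs at least two samples")
    if np.any(x < 0) or np.any(x > arena.width_cm) or np.any(y < 0) or np.any(
        y > arena.height_cm
    ):
        raise ValueError("trajectory leaves the arena bounds")
    half = arena.center_side_cm / 2.0
    cx, cy = arena.width_cm / 2.0, arena.height_cm / 2.0
    inside = (np.abs(x - cx) <= half) & (np.abs(y - cy) <= half)
    w = _dwell_weights(t)
    frac = float(w[inside].sum() / w.sum())
    seg = np.hypot(np.diff(x), np.diff(y))
    both_in = inside[:-1] & inside[1:]
    dist = float(seg[both_in].sum())
    return frac, dist
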