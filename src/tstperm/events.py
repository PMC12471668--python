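"""Dividing-plane crossing events and the recrossing correction κ.

The transition-state-theory estimate of the water transport rate counts
crossings of the dividing plane (the channel's most constricted point,
``z = z_divide``) and corrects for recrossing: a crossing only contributes
to transport if the molecule goes on to reach the opposite bulk reservoir
instead of returning.  Two quantities are measured on each track:

* **events** — every dividing-plane crossing is followed until it either
  *recrosses* the plane back to its starting side (or exits the pore
  sideways), or *succeeds* by reaching the destination bulk
  (``z >= z_bulk_ec`` for IC→EC, ``z <= z_bulk_ic`` for EC→IC).  A
  successful event is, by construction, the final leg of a complete
  bulk-to-bulk traversal, so the number of successes equals the number
  of complete permeation events.
* **raw crossings** — every sign change of ``z − z_divide`` between
  consecutive stored frames (while laterally inside the pore).  This is
  the denominator of the transmission coefficient
  ``κ = successes / crossings``; paired with the Maxwell–Boltzmann flux
  it yields the TST rate constant (see :mod:`tstperm.tst`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .errors import DataError
from .trajectory import ChannelFrame, ParticleTrack

logger = logging.getLogger(__name__)

#: direction labels
IC_TO_EC = "IC->EC"
EC_TO_IC = "EC->IC"

_SUCCESS, _RECROSS, _UNRESOLVED = 1, 0, -1
_OUTCOME_NAMES = {_SUCCESS: "success", _RECROSS: "recross",
                  _UNRESOLVED: "unresolved"}


@dataclass(frozen=True)
class CrossingEvent:
    """One dividing-plane crossing followed to resolution."""

    particle_id: int
    monomer_id: str
    t_cross: float
    direction: str  # IC_TO_EC or EC_TO_IC
    outcome: str  # "success" | "recross" | "unresolved"
    t_resolve: float | None = None

    def __post_init__(self) -> None:
        if self.t_resolve is not None and self.t_resolve < self.t_cross:
            raise DataError("t_resolve must be >= t_cross")


@njit(cache=True)
def _event_machine(z, lat, times, z_divide, z_bulk_ec, z_bulk_ic,
                   t_cross, direction, outcome, t_resolve):
    """Sequential crossing-event state machine on one track.

    An event opens at an eligible sign change of (z - z_divide); while it
    is open no further events open for this particle; the pair of frames
    that resolves an event is consumed (it does not itself open a new
    event); after resolution the particle is immediately eligible again.
    Returns the number of events written.
    """
    n = z.shape[0]
    n_ev = 0
    open_dir = 0  # 0 none, +1 IC->EC, -1 EC->IC
    for i in range(1, n):
        if open_dir != 0:
            # 0 = still open, 1 = success, 2 = recross(-equivalent)
            resolved = 0
            if open_dir == 1:
                if z[i] >= z_bulk_ec:
                    resolved = 1
                elif z[i] < z_divide or not lat[i]:
                    resolved = 2
            else:
                if z[i] <= z_bulk_ic:
                    resolved = 1
                elif z[i] >= z_divide or not lat[i]:
                    resolved = 2
            if resolved != 0:
                outcome[n_ev - 1] = _SUCCESS if resolved == 1 else _RECROSS
                t_resolve[n_ev - 1] = times[i]
                open_dir = 0
            continue
        below_prev = z[i - 1] < z_divide
        below_now = z[i] < z_divide
        if below_prev != below_now and lat[i - 1] and lat[i]:
            d = 1 if below_prev else -1
            t_cross[n_ev] = times[i]
            direction[n_ev] = d
            outcome[n_ev] = _UNRESOLVED
            t_resolve[n_ev] = np.nan
            n_ev += 1
            open_dir = d
            # a single stored step may jump straight into the bulk
            if d == 1 and z[i] >= z_bulk_ec:
                outcome[n_ev - 1] = _SUCCESS
                t_resolve[n_ev - 1] = times[i]
                open_dir = 0
            elif d == -1 and z[i] <= z_bulk_ic:
                outcome[n_ev - 1] = _SUCCESS
                t_resolve[n_ev - 1] = times[i]
                open_dir = 0
    return n_ev


def detect_events(track: ParticleTrack, frame: ChannelFrame,
                  monomer_id: str | None = None) -> list[CrossingEvent]:
    """Detect dividing-plane crossing events on one particle track.

    Crossings are detected as sign changes of ``z − z_divide`` between
    consecutive stored frames (the crossing time is the later frame); an
    open event resolves as *success* on arrival in the destination bulk,
    as *recross* when the plane is crossed back, and as recross-equivalent
    failure when the particle leaves the lateral gate inside the slab.
    Events still open at the last frame are returned as *unresolved* and
    are excluded from κ entirely.
    """
    z = np.ascontiguousarray(track.z, dtype=np.float64)
    if track.times.size >= 2 and not np.all(np.diff(track.times) > 0):
        raise DataError("track times must be strictly increasing")
    lat = (
        np.ones(z.shape, dtype=np.bool_)
        if track.lateral_ok is None
        else np.ascontiguousarray(track.lateral_ok, dtype=np.bool_)
    )
    times = np.ascontiguousarray(track.times, dtype=np.float64)
    s = z - frame.z_divide
    max_ev = int(np.count_nonzero((s[:-1] < 0) != (s[1:] < 0))) + 1
    t_cross = np.empty(max_ev)
    direction = np.empty(max_ev, dtype=np.int64)
    outcome = np.empty(max_ev, dtype=np.int64)
    t_resolve = np.empty(max_ev)
    n_ev = _event_machine(z, lat, times, frame.z_divide, frame.z_bulk_ec,
                          frame.z_bulk_ic, t_cross, direction, outcome,
                          t_resolve)
    mono = monomer_id if monomer_id is not None else frame.monomer_id
    return [
        CrossingEvent(
            particle_id=track.particle_id,
            monomer_id=mono,
            t_cross=float(t_cross[j]),
            direction=IC_TO_EC if direction[j] == 1 else EC_TO_IC,
            outcome=_OUTCOME_NAMES[int(outcome[j])],
            t_resolve=None if outcome[j] == _UNRESOLVED else float(t_resolve[j]),
        )
        for j in range(n_ev)
    ]


def plane_crossing_times(
    track: ParticleTrack, frame: ChannelFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Times of every raw (eligible) dividing-plane crossing.

    Returns ``(t_up, t_down)``: times of upward (IC→EC direction) and
    downward sign changes of ``z − z_divide``, subject to the same
    lateral-eligibility rule as :func:`detect_events`.  These raw counts
    form the denominator of κ and, divided by observation time, the
    measured one-way crossing rate of the TST flux.
    """
    s = np.asarray(track.z, dtype=float) - frame.z_divide
    below = s < 0
    changed = below[:-1] != below[1:]
    if track.lateral_ok is not None:
        lat = np.asarray(track.lateral_ok, dtype=bool)
        changed &= lat[:-1] & lat[1:]
    up = changed & below[:-1]
    down = changed & ~below[:-1]
    t = np.asarray(track.times, dtype=float)[1:]
    return t[up], t[down]


def count_plane_crossings(track: ParticleTrack,
                          frame: ChannelFrame) -> tuple[int, int]:
    """Raw (up, down) dividing-plane crossing counts for one track."""
    t_up, t_down = plane_crossing_times(track, frame)
    return int(t_up.size), int(t_down.size)


@dataclass
class EventSummary:
    """Pooled event statistics over an observation window.

    ``kappa`` is the transmission (recrossing) correction: successful
    transport events divided by the total number of dividing-plane
    crossings.  When raw crossing counts were not supplied it falls back
    to successes over state-machine attempts (``success_ratio_attempts``);
    the ``kappa_denominator`` field records which was used.
    """

    attempts_total: int
    successes_total: int
    attempts_by_direction: dict[str, int]
    successes_by_direction: dict[str, int]
    kappa: float | None
    cumulative: pd.DataFrame
    observation_time: float
    n_monomers: int = 1
    crossings_total: int | None = None
    crossings_by_direction: dict[str, int] | None = None
    unresolved_total: int = 0
    kappa_denominator: str = "crossings"

    @property
    def success_ratio_attempts(self) -> float | None:
        if self.attempts_total == 0:
            return None
        return self.successes_total / self.attempts_total

    def to_json_dict(self) -> dict:
        d = {
            "attempts_total": self.attempts_total,
            "successes_total": self.successes_total,
            "attempts_by_direction": self.attempts_by_direction,
            "successes_by_direction": self.successes_by_direction,
            "kappa": self.kappa,
            "kappa_denominator": self.kappa_denominator,
            "crossings_total": self.crossings_total,
            "unresolved_total": self.unresolved_total,
            "observation_time_ps": self.observation_time,
            "n_monomers": self.n_monomers,
        }
        return d


def summarize_events(
    events: list[CrossingEvent],
    observation_time: float,
    time_grid: np.ndarray | None = None,
    crossing_times: tuple[np.ndarray, np.ndarray] | None = None,
    n_monomers: int = 1,
) -> EventSummary:
    """Pool events into totals, κ, and cumulative (0, t) time series.

    Parameters
    ----------
    events:
        Detected events (possibly pooled over particles and monomers).
    observation_time:
        Length of the observation window (ps).
    time_grid:
        Grid for the cumulative series; defaults to 50 evenly spaced
        points over the window.
    crossing_times:
        Optional ``(t_up, t_down)`` arrays of raw plane crossings (from
        :func:`plane_crossing_times`, pooled).  When given, κ uses the raw
        crossing count as its denominator (the transmission-coefficient
        definition); otherwise successes/attempts is used and flagged.

    Unresolved events count in neither numerator nor denominator.
    Cumulative counts are non-decreasing step functions; κ(0, t) uses only
    events (and crossings) with resolution/crossing time ≤ t.
    """
    if not observation_time > 0:
        raise DataError("observation_time must be positive")
    resolved = [e for e in events if e.outcome != "unresolved"]
    successes = [e for e in resolved if e.outcome == "success"]
    attempts_by = {IC_TO_EC: 0, EC_TO_IC: 0}
    succ_by = {IC_TO_EC: 0, EC_TO_IC: 0}
    for e in resolved:
        attempts_by[e.direction] += 1
        if e.outcome == "success":
            succ_by[e.direction] += 1

    crossings_total = None
    crossings_by = None
    if crossing_times is not None:
        t_up, t_down = crossing_times
        crossings_by = {IC_TO_EC: int(np.size(t_up)),
                        EC_TO_IC: int(np.size(t_down))}
        crossings_total = crossings_by[IC_TO_EC] + crossings_by[EC_TO_IC]

    n_attempts = len(resolved)
    n_success = len(successes)
    if crossings_total is not None and crossings_total > 0:
        kappa = n_success / crossings_total
        denom = "crossings"
    elif n_attempts > 0:
        kappa = n_success / n_attempts
        denom = "attempts"
    else:
        kappa = None
        denom = "undefined"
        logger.warning("no resolved events: kappa undefined")

    if time_grid is None:
        time_grid = np.linspace(0.0, observation_time, 51)[1:]
    time_grid = np.asarray(time_grid, dtype=float)

    t_res = np.array([e.t_resolve for e in resolved], dtype=float)
    t_res_s = np.array(
        [e.t_resolve for e in successes], dtype=float
    )
    cum_attempts = np.searchsorted(np.sort(t_res), time_grid, side="right")
    cum_succ = np.searchsorted(np.sort(t_res_s), time_grid, side="right")
    if crossing_times is not None:
        all_cross = np.sort(np.concatenate([crossing_times[0],
                                            crossing_times[1]]))
        cum_cross = np.searchsorted(all_cross, time_grid, side="right")
        with np.errstate(invalid="ignore", divide="ignore"):
            cum_kappa = np.where(cum_cross > 0, cum_succ / np.maximum(cum_cross, 1),
                                 np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            cum_kappa = np.where(cum_attempts > 0,
                                 cum_succ / np.maximum(cum_attempts, 1), np.nan)
    cumulative = pd.DataFrame(
        {
            "t_ps": time_grid,
            "attempts": cum_attempts,
            "successes": cum_succ,
            "kappa": cum_kappa,
        }
    )

    return EventSummary(
        attempts_total=n_attempts,
        successes_total=n_success,
        attempts_by_direction=attempts_by,
        successes_by_direction=succ_by,
        kappa=kappa,
        cumulative=cumulative,
        observation_time=float(observation_time),
        n_monomers=n_monomers,
        crossings_total=crossings_total,
        crossings_by_direction=crossings_by,
        unresolved_total=len(events) - n_attempts,
        kappa_denominator=denom,
    )


class EventAccumulator:
    """Streaming accumulator for large trajectories.

    Feeds tracks one at a time (so multi-gigabyte runs never need all
    tracks in memory) and produces the same :class:`EventSummary` as the
    pooled path.  Event times are kept; per-event objects are discarded
    unless ``keep_events`` is set.
    """

    def __init__(self, frame: ChannelFrame, keep_events: bool = False):
        self.frame = frame
        self.keep_events = keep_events
        self.events: list[CrossingEvent] = []
        self._t_resolve: list[np.ndarray] = []
        self._t_resolve_success: list[np.ndarray] = []
        self._t_up: list[np.ndarray] = []
        self._t_down: list[np.ndarray] = []
        self.attempts_by = {IC_TO_EC: 0, EC_TO_IC: 0}
        self.successes_by = {IC_TO_EC: 0, EC_TO_IC: 0}
        self.unresolved = 0

    def add_track(self, track: ParticleTrack) -> None:
        events = detect_events(track, self.frame)
        if self.keep_events:
            self.events.extend(events)
        res = [e for e in events if e.outcome != "unresolved"]
        self.unresolved += len(events) - len(res)
        self._t_resolve.append(
            np.array([e.t_resolve for e in res], dtype=float))
        self._t_resolve_success.append(
            np.array([e.t_resolve for e in res if e.outcome == "success"],
                     dtype=float))
        for e in res:
            self.attempts_by[e.direction] += 1
            if e.outcome == "success":
                self.successes_by[e.direction] += 1
        t_up, t_down = plane_crossing_times(track, self.frame)
        self._t_up.append(t_up)
        self._t_down.append(t_down)

    @property
    def crossings_up(self) -> int:
        return int(sum(a.size for a in self._t_up))

    @property
    def crossings_down(self) -> int:
        return int(sum(a.size for a in self._t_down))

    def summarize(self, observation_time: float,
                  time_grid: np.ndarray | None = None,
                  n_monomers: int = 1) -> EventSummary:
        succ_times = np.concatenate(self._t_resolve_success) if \
            self._t_resolve_success else np.empty(0)
        all_times = np.concatenate(self._t_resolve) if self._t_resolve \
            else np.empty(0)
        summary = summarize_events(
            self.events if self.keep_events else _pseudo_events(
                all_times, succ_times, self.frame.monomer_id),
            observation_time,
            time_grid=time_grid,
            crossing_times=(
                np.concatenate(self._t_up) if self._t_up else np.empty(0),
                np.concatenate(self._t_down) if self._t_down else np.empty(0),
            ),
            n_monomers=n_monomers,
        )
        # per-direction tallies from the exact per-track bookkeeping
        summary.attempts_by_direction = dict(self.attempts_by)
        summary.successes_by_direction = dict(self.successes_by)
        summary.unresolved_total = self.unresolved
        return summary


def _pseudo_events(all_times: np.ndarray, succ_times: np.ndarray,
                   monomer_id: str) -> list[CrossingEvent]:
    """Rebuild minimal events (times + outcomes) from pooled time arrays."""
    succ_sorted = np.sort(succ_times)
    events = []
    used = np.zeros(succ_sorted.size, dtype=bool)
    for t in all_times:
        j = np.searchsorted(succ_sorted, t)
        while j < succ_sorted.size and succ_sorted[j] == t and used[j]:
            j += 1
        is_succ = False
        if j < succ_sorted.size and succ_sorted[j] == t:
            used[j] = True
            is_succ = True
        events.append(
            CrossingEvent(-1, monomer_id, t, IC_TO_EC,
                          "success" if is_succ else "recross", t)
        )
    return events


def events_to_dataframe(events: list[CrossingEvent]) -> pd.DataFrame:
    """One row per event; suitable for TSV export."""
    return pd.DataFrame(
        {
            "particle_id": [e.particle_id for e in events],
            "monomer_id": [e.monomer_id for e in events],
            "t_cross_ps": [e.t_cross for e in events],
            "direction": [e.direction for e in events],
            "outcome": [e.outcome for e in events],
            "t_resolve_ps": [e.t_resolve for e in events],
        }
    )


def plot_event_counts(summary: EventSummary, success_scale: float = 50.0,
                      ax=None):
    """Cumulative attempts and (scaled) successes versus time.

    The success curve is multiplied by ``success_scale`` so both curves
    share one axis; the factor is cosmetic and never enters κ or p_f.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cum = summary.cumulative
    if len(cum) == 0:
        warnings.warn("empty cumulative grid: producing empty figure")
        return ax.figure
    ax.plot(cum["t_ps"], cum["attempts"], label="attempts (0, t)")
    ax.plot(
        cum["t_ps"],
        success_scale * cum["successes"],
        label=f"successes (0, t) × {success_scale:g}",
    )
    ax.set_xlabel("t (ps)")
    ax.set_ylabel("cumulative count")
    ax.legend()
    return ax.figure
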