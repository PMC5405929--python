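"""Persistence estimation: partition medication histories into treatment
episodes.

A *treatment episode* is a maximal run of medication events in which the time
from the end of one event's supply (with carry-over, per policy) to the start
of the next event never exceeds a researcher-defined *permissible gap*.
Optionally a change of medication category also starts a new episode.

End-date semantics (all half-open, ``duration == end - start``):

* an episode closed by an over-long gap ends at the supply-exhaustion point;
  the trailing gap counts the days to the next episode's start;
* an episode closed by a medication change ends at ``min(exhaustion, change
  event date)`` — the change event both ends the old episode and starts the
  new one, so overlapping old supply is handed to the carry-over policy and
  never double-counted;
* the final episode ends at the FUW end if its trailing gap (exhaustion to
  FUW end) is within the permissible gap, else at the exhaustion point; the
  trailing gap is reported either way.

Carry-over state resets at every episode start: a discontinuation is a reset
of the supply ledger, so surplus (including category-frozen surplus) never
leaks across episodes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date
from fractions import Fraction

import pandas as pd

from .coverage_engine import CarryoverPolicy, Event, _Sweep, events_from_frame
from .event_store import EventTable
from .windows import Duration, WindowSpec, resolve_window

__all__ = ["EpisodePolicy", "EpisodeRecord", "compute_treatment_episodes",
           "episodes_to_frame", "select_episode"]

_GAP_UNITS = ("days", "weeks", "months", "years", "percent")


@dataclass(frozen=True)
class EpisodePolicy:
    """Parameters of episode detection.

    ``permissible_gap`` is interpreted via ``gap_unit``: days/weeks/months/
    years (weeks = 7 days; months/years use calendar arithmetic from the gap
    start), or ``"percent"`` — percent of the duration of the episode's most
    recent event.
    """

    permissible_gap: float = 90
    gap_unit: str = "days"
    medication_change_new_episode: bool = False
    carryover: CarryoverPolicy = field(default_factory=CarryoverPolicy)

    def __post_init__(self) -> None:
        if self.permissible_gap < 0:
            raise ValueError("permissible_gap must be >= 0")
        if self.gap_unit not in _GAP_UNITS:
            raise ValueError(f"gap_unit must be one of {_GAP_UNITS}")

    def gap_limit_days(self, gap_start: date, last_event: Event) -> float:
        if self.gap_unit == "days":
            return float(self.permissible_gap)
        if self.gap_unit == "weeks":
            return float(self.permissible_gap) * 7
        if self.gap_unit == "percent":
            return float(self.permissible_gap) / 100.0 * last_event.duration
        end = Duration(int(self.permissible_gap), self.gap_unit).add_to(gap_start)
        return float((end - gap_start).days)


@dataclass(frozen=True)
class EpisodeRecord:
    patient_id: object
    episode_index: int  # 1-based
    start_date: date
    end_date: date
    duration_days: int
    trailing_gap_days: int

    def __post_init__(self) -> None:
        assert self.duration_days == (self.end_date - self.start_date).days


def _ceil_date(x: Fraction) -> date:
    return date.fromordinal(math.ceil(x))


def _patient_episodes(pid, events: list[Event], fuw_start: int, fuw_end: int,
                      policy: EpisodePolicy) -> list[EpisodeRecord]:
    events = [e for e in events if fuw_start <= e.t < fuw_end]
    if not events:
        return []
    records: list[EpisodeRecord] = []
    i = 0
    ep_start = events[0].t
    sweep = _Sweep(policy.carryover)
    supply_end = sweep.feed(events[0])
    last_event = events[0]

    def close(end_ord: Fraction, next_start: int | None) -> None:
        """Close the current episode at ``end_ord`` (ceil to whole days)."""
        end = min(math.ceil(end_ord), fuw_end)
        until = next_start if next_start is not None else fuw_end
        records.append(
            EpisodeRecord(
                patient_id=pid,
                episode_index=len(records) + 1,
                start_date=date.fromordinal(ep_start),
                end_date=date.fromordinal(end),
                duration_days=end - ep_start,
                trailing_gap_days=until - end,
            )
        )

    for ev in events[1:]:
        gap = float(ev.t - supply_end)
        gap_start = _ceil_date(min(supply_end, Fraction(ev.t)))
        changed = (policy.medication_change_new_episode
                   and ev.category != last_event.category)
        if changed or gap > policy.gap_limit_days(gap_start, last_event):
            # medication change takes precedence; both close the episode at
            # min(exhaustion, new event date)
            close(min(supply_end, Fraction(ev.t)), next_start=ev.t)
            ep_start = ev.t
            sweep = _Sweep(policy.carryover)  # discontinuation resets supply
            supply_end = sweep.feed(ev)
        else:
            supply_end = sweep.feed(ev)
        last_event = ev

    # final episode: extend to FUW end when still within the permissible gap
    exhaustion = min(math.ceil(supply_end), fuw_end)
    trailing = fuw_end - exhaustion
    gap_start = date.fromordinal(exhaustion)
    if trailing <= policy.gap_limit_days(gap_start, last_event):
        records.append(
            EpisodeRecord(
                patient_id=pid,
                episode_index=len(records) + 1,
                start_date=date.fromordinal(ep_start),
                end_date=date.fromordinal(fuw_end),
                duration_days=fuw_end - ep_start,
                trailing_gap_days=trailing,
            )
        )
    else:
        close(Fraction(exhaustion), next_start=None)
    return records


def compute_treatment_episodes(events: EventTable, window_spec: WindowSpec,
                               policy: EpisodePolicy) -> list[EpisodeRecord]:
    """Detect treatment episodes for every patient in ``events``.

    Patients with no events inside their FUW yield no records (with a
    warning).  Records are ordered by (patient input order, episode index).
    """
    out: list[EpisodeRecord] = []
    for pid in events.patient_ids:
        df = events.for_patient(pid)
        evs = events_from_frame(df)
        win = resolve_window(window_spec, evs[0].date if evs else None)
        recs = _patient_episodes(pid, evs, win.fuw_start.toordinal(),
                                 win.fuw_end.toordinal(), policy)
        if not recs:
            warnings.warn(f"patient {pid!r}: no events in FUW, skipped")
        out.extend(recs)
    return out


def episodes_to_frame(records: list[EpisodeRecord]) -> pd.DataFrame:
    """Long-format table with the standard column semantics (ISO dates)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "episode_number": r.episode_index,
                "episode_start": r.start_date.isoformat(),
                "gap_days": r.trailing_gap_days,
                "episode_duration": r.duration_days,
                "episode_end": r.end_date.isoformat(),
            }
            for r in records
        ]
    )


def select_episode(records: list[EpisodeRecord], which: str = "first"
                   ) -> list[EpisodeRecord]:
    """Per-patient selector for time-to-event analyses (first/last episode)."""
    if which not in ("first", "last"):
        raise ValueError("which must be 'first' or 'last'")
    by_pid: dict[object, list[EpisodeRecord]] = {}
    for r in records:
        by_pid.setdefault(r.patient_id, []).append(r)
    pick = (lambda rs: rs[0]) if which == "first" else (lambda rs: rs[-1])
    return [pick(sorted(rs, key=lambda r: r.episode_index))
            for rs in by_pid.values()]
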