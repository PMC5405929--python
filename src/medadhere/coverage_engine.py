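"""Carry-over supply engine: event lists -> coverage timelines.

The model: each medication event deposits ``duration_days`` of supply, which
is consumed from the event date onward at the recommended rate (supplied =
used).  If a new event arrives while supply remains, the surplus days can be
*carried over* and queued behind the new supply.  Two refinements mirror
clinical practice:

* ``same_medication_only`` — surplus carries only between events of the same
  medication category.  When the category changes while supply remains, the
  old category's surplus is frozen (consumption switches to the newly supplied
  medication) and resumes only at a later event of the frozen category; it is
  never destroyed within one sweep.
* ``consider_dosage_change`` — when the daily dose changes, surplus days are
  converted through the pill count: ``surplus_days * old_dose / new_dose``.
  Converted amounts are kept as exact rationals (:class:`fractions.Fraction`);
  nothing is rounded inside the engine.

Without ``carryover_within_ow`` the covered period is simply the union of the
per-event intervals ``[date, date + duration)`` and any overlap is lost.

All timelines are expressed on an integer day axis (``datetime.date``
ordinals); intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from fractions import Fraction

import pandas as pd

__all__ = [
    "Event",
    "CarryoverPolicy",
    "CoverageTimeline",
    "build_coverage",
    "interval_supply_ratios",
    "events_from_frame",
]


@dataclass(frozen=True)
class Event:
    """One medication event on the integer day axis (``date.toordinal()``)."""

    t: int
    duration: int
    dose: Fraction | None
    category: str

    @property
    def date(self) -> date:
        return date.fromordinal(self.t)


def events_from_frame(df: pd.DataFrame) -> list[Event]:
    """Convert one patient's (date-sorted) event rows to engine events."""
    out = []
    for row in df.itertuples(index=False):
        dose = None if pd.isna(row.daily_dose) else Fraction(row.daily_dose).limit_denominator(10**6)
        out.append(
            Event(
                t=row.event_date.date().toordinal(),
                duration=int(row.duration_days),
                dose=dose,
                category="" if pd.isna(row.category) else str(row.category),
            )
        )
    return out


@dataclass(frozen=True)
class CarryoverPolicy:
    carryover_within_ow: bool = True
    same_medication_only: bool = False
    consider_dosage_change: bool = False
    carryover_into_ow: bool = False

    def __post_init__(self) -> None:
        if (self.same_medication_only or self.consider_dosage_change) and not self.carryover_within_ow:
            raise ValueError(
                "same_medication_only / consider_dosage_change require carryover_within_ow"
            )


@dataclass
class CoverageTimeline:
    """Result of a sweep: disjoint covered intervals plus bookkeeping.

    ``covered`` are half-open ``(start, end)`` pairs on the day axis (ends may
    be fractional after dose conversion).  ``supply_end_after_event[i]`` is
    the exhaustion point of the supply governing refill gaps right after event
    ``i`` was processed — the quantity episode detection compares against the
    next event date.  ``residual_supply_at_end`` is the active supply (days)
    left beyond the span end; ``frozen_supply`` maps categories to surplus
    days parked by ``same_medication_only``.
    """

    covered: list[tuple[Fraction, Fraction]] = field(default_factory=list)
    supply_end_after_event: list[Fraction] = field(default_factory=list)
    residual_supply_at_end: Fraction = Fraction(0)
    frozen_supply: dict[str, Fraction] = field(default_factory=dict)
    interval_ratios: list[tuple[int, int, Fraction]] = field(default_factory=list)

    def covered_days_in(self, start, end) -> Fraction:
        """Total covered time within ``[start, end)``."""
        total = Fraction(0)
        for a, b in self.covered:
            lo, hi = max(a, Fraction(start)), min(b, Fraction(end))
            if hi > lo:
                total += hi - lo
        return total

    def gap_days_in(self, start, end) -> Fraction:
        return Fraction(end) - Fraction(start) - self.covered_days_in(start, end)

    def ratio_weight_in(self, start, end) -> Fraction:
        """Sum of per-day supply ratios over ``[start, end)`` (ratio mode)."""
        total = Fraction(0)
        for a, b, r in self.interval_ratios:
            lo, hi = max(a, start), min(b, end)
            if hi > lo:
                total += (hi - lo) * r
        return total


def _convert(surplus: Fraction, old_dose, new_dose, consider: bool) -> Fraction:
    if not consider or old_dose is None or new_dose is None or old_dose == new_dose:
        return surplus
    return surplus * old_dose / new_dose


class _Sweep:
    """Sequential consumption state shared by coverage and episode logic."""

    def __init__(self, policy: CarryoverPolicy):
        self.policy = policy
        self.cur_end: Fraction | None = None  # active supply exhaustion
        self.cur_dose = None
        self.cur_cat: str | None = None
        self.frozen: dict[str, tuple[Fraction, object]] = {}  # cat -> (days, dose)
        self.covered: list[list[Fraction]] = []

    def _emit(self, start: Fraction, end: Fraction) -> None:
        if end <= start:
            return
        if self.covered and self.covered[-1][1] >= start:
            self.covered[-1][1] = max(self.covered[-1][1], end)
        else:
            self.covered.append([start, end])

    def feed(self, ev: Event) -> Fraction:
        """Process one event; return the governing supply-exhaustion point."""
        p, t = self.policy, Fraction(ev.t)
        if not p.carryover_within_ow:
            # no carry-over: a new event discards whatever supply remained
            if self.covered:
                self.covered[-1][1] = min(self.covered[-1][1], t)
            self._emit(t, t + ev.duration)
            self.cur_end = t + ev.duration
            self.cur_cat, self.cur_dose = ev.category, ev.dose
            return t + ev.duration

        surplus = Fraction(0)
        if self.cur_end is not None and self.cur_end > t:
            active_surplus = self.cur_end - t
            if p.same_medication_only and ev.category != self.cur_cat:
                # consumption switches medication: park the old surplus
                days, dose = self.frozen.get(self.cur_cat, (Fraction(0), self.cur_dose))
                self.frozen[self.cur_cat] = (days + active_surplus, self.cur_dose)
                if self.covered:  # active coverage stops at the switch
                    self.covered[-1][1] = min(self.covered[-1][1], t)
            else:
                surplus = _convert(active_surplus, self.cur_dose, ev.dose,
                                   p.consider_dosage_change)
                # coverage beyond the event date is superseded: the surplus is
                # re-expressed (possibly shrunk/stretched by a dose change)
                # and re-deposited from the event date onward
                if self.covered:
                    self.covered[-1][1] = min(self.covered[-1][1], t)
        if p.same_medication_only and ev.category in self.frozen:
            days, dose = self.frozen.pop(ev.category)
            surplus += _convert(days, dose, ev.dose, p.consider_dosage_change)

        new_end = t + surplus + ev.duration
        self._emit(t, new_end)
        self.cur_end, self.cur_cat, self.cur_dose = new_end, ev.category, ev.dose
        return new_end


def build_coverage(events: list[Event], span_start, span_end,
                   policy: CarryoverPolicy) -> CoverageTimeline:
    """Sweep ``events`` (sorted by date, input order) into a coverage timeline.

    ``span_start``/``span_end`` bound the reported timeline (day ordinals or
    dates); events outside are assumed already filtered by the caller — which
    events participate (e.g. pre-window supply carried in) is window policy,
    not engine policy.  Covered intervals are clipped to the span; residual
    supply beyond ``span_end`` is reported, not counted.
    """
    a = span_start.toordinal() if isinstance(span_start, date) else span_start
    b = span_end.toordinal() if isinstance(span_end, date) else span_end
    sweep = _Sweep(policy)
    ends = [sweep.feed(ev) for ev in events]
    tl = CoverageTimeline(supply_end_after_event=ends)
    for lo, hi in sweep.covered:
        lo2, hi2 = max(lo, Fraction(a)), min(hi, Fraction(b))
        if hi2 > lo2:
            tl.covered.append((lo2, hi2))
    last = sweep.cur_end if sweep.cur_end is not None else Fraction(a)
    tl.residual_supply_at_end = max(Fraction(0), last - Fraction(b))
    tl.frozen_supply = {c: d for c, (d, _) in sweep.frozen.items()}
    return tl


def interval_supply_ratios(events: list[Event], span_start, span_end,
                           policy: CarryoverPolicy) -> CoverageTimeline:
    """Per inter-event-interval supply ratios (the CMA9 primitive).

    For each event, the interval runs from its date to the next event's date
    (FUW end for the last event).  The ratio is ``min(1, supply/interval)``
    where supply is the event's duration plus any surplus carried from
    previous intervals (dose-converted / category-restricted per ``policy``);
    oversupply beyond ratio 1 carries into the next interval.  Days before
    the first event have ratio 0.  Same-date events pool their supply into
    the following interval.
    """
    a = span_start.toordinal() if isinstance(span_start, date) else span_start
    b = span_end.toordinal() if isinstance(span_end, date) else span_end
    tl = CoverageTimeline()
    if not events:
        tl.interval_ratios.append((a, b, Fraction(0)))
        return tl
    if events[0].t > a:
        tl.interval_ratios.append((a, events[0].t, Fraction(0)))

    carry: dict[str, tuple[Fraction, object]] = {}  # cat -> (days, dose); "" pools all
    p = policy

    def key(cat: str) -> str:
        return cat if p.same_medication_only else ""

    for i, ev in enumerate(events):
        nxt = events[i + 1].t if i + 1 < len(events) else b
        supply = Fraction(ev.duration)
        k = key(ev.category)
        if k in carry:
            days, dose = carry.pop(k)
            supply += _convert(days, dose, ev.dose, p.consider_dosage_change)
        length = max(0, nxt - ev.t)
        if length == 0:
            carry[k] = (supply, ev.dose)
            continue
        ratio = min(Fraction(1), supply / length)
        leftover = supply - min(supply, Fraction(length))
        if leftover > 0 and p.carryover_within_ow:
            carry[k] = (leftover, ev.dose)
        tl.interval_ratios.append((ev.t, nxt, ratio))

    tl.frozen_supply = {c: d for c, (d, _) in carry.items()}
    return tl
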