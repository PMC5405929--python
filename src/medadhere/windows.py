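"""Resolution of symbolic follow-up / observation windows to date intervals.

Terminology: the *follow-up window* (FUW) is the total period over which a
patient's medication events are considered; the *observation window* (OW) is
the sub-period over which an adherence estimate is computed.  Both are
half-open day intervals ``[start, end)``: a 730-day FUW starting 2035-12-13
ends on 2037-12-12 (exclusive bound; last included day 2037-12-11).  Reported
"end dates" throughout the package are these exclusive bounds, so that
``duration == end - start`` always holds, including across leap years.

Day/week offsets add exact day counts; month/year offsets use calendar
arithmetic with end-of-month clamping (Jan 31 + 1 month = Feb 28/29).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

from dateutil.relativedelta import relativedelta

_UNITS = ("days", "weeks", "months", "years")


@dataclass(frozen=True)
class Duration:
    """A signed calendar amount: days, weeks, months or years."""

    amount: int
    unit: str = "days"

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")

    def add_to(self, d: date) -> date:
        if self.unit == "days":
            return d + timedelta(days=self.amount)
        if self.unit == "weeks":
            return d + timedelta(weeks=self.amount)
        if self.unit == "months":
            return d + relativedelta(months=self.amount)
        return d + relativedelta(years=self.amount)


def _as_duration(x) -> Duration:
    if isinstance(x, Duration):
        return x
    if isinstance(x, int):
        return Duration(x, "days")
    raise TypeError(f"expected Duration or int day count, got {type(x)!r}")


class WindowSpecError(ValueError):
    """The window specification cannot be resolved (OW outside FUW...)."""


@dataclass(frozen=True)
class WindowSpec:
    """Symbolic FUW/OW specification, resolved per patient.

    ``fuw_anchor`` is either the string ``"first_event"`` (FUW starts at the
    patient's first recorded event) or a fixed calendar :class:`datetime.date`.
    Offsets/durations accept plain ints (day counts) or :class:`Duration`.
    ``ow_duration=None`` means the OW extends to the FUW end.
    """

    fuw_anchor: object = "first_event"
    fuw_offset: object = 0
    fuw_duration: object = 730
    ow_offset: object = 0  # from FUW start
    ow_duration: object | None = None

    def resolve(self, first_event_date: date | None = None) -> "ResolvedWindow":
        return resolve_window(self, first_event_date)


@dataclass(frozen=True)
class ResolvedWindow:
    """Concrete half-open FUW and OW date intervals for one patient."""

    fuw_start: date
    fuw_end: date
    ow_start: date
    ow_end: date

    def __post_init__(self) -> None:
        if not (self.fuw_start <= self.ow_start < self.ow_end <= self.fuw_end):
            raise WindowSpecError(
                f"OW [{self.ow_start}, {self.ow_end}) must lie within "
                f"FUW [{self.fuw_start}, {self.fuw_end})"
            )

    @property
    def fuw_days(self) -> int:
        return (self.fuw_end - self.fuw_start).days

    @property
    def ow_days(self) -> int:
        return (self.ow_end - self.ow_start).days

    def with_ow(self, ow_start: date, ow_end: date) -> "ResolvedWindow":
        return ResolvedWindow(self.fuw_start, self.fuw_end, ow_start, ow_end)


def resolve_window(spec: WindowSpec, first_event_date: date | None = None
                   ) -> ResolvedWindow:
    """Resolve a :class:`WindowSpec` for one patient.

    A pure function of the spec and the patient's first event date (the latter
    only required for the ``"first_event"`` anchor).
    """
    if spec.fuw_anchor == "first_event":
        if first_event_date is None:
            raise WindowSpecError("per-patient anchor requires a first event date")
        anchor = first_event_date
    elif isinstance(spec.fuw_anchor, date):
        anchor = spec.fuw_anchor
    else:
        raise WindowSpecError(f"bad fuw_anchor: {spec.fuw_anchor!r}")
    fuw_start = _as_duration(spec.fuw_offset).add_to(anchor)
    fuw_end = _as_duration(spec.fuw_duration).add_to(fuw_start)
    ow_start = _as_duration(spec.ow_offset).add_to(fuw_start)
    if spec.ow_duration is None:
        ow_end = fuw_end
    else:
        ow_end = _as_duration(spec.ow_duration).add_to(ow_start)
    return ResolvedWindow(fuw_start, fuw_end, ow_start, ow_end)
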