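"""The nine simple continuous-multiple-interval measures of medication
availability (CMA1-CMA9), evaluated over one observation window per patient.

The variants differ along four axes: how the evaluated span is anchored
(first event -> last event vs. first event / OW start -> OW end), whether the
ratio is capped at 100%, whether oversupply carries over between events, and
whether supply from before the OW start is credited (CMA7-9):

====  ==========================================================  ==========
CMA   numerator / denominator                                      carry-over
====  ==========================================================  ==========
1     sum of event durations excluding the last event /
      first OW event to last OW event                              none
2     sum of all event durations / first OW event to OW end        none
3, 4  CMA1, CMA2 capped at 100%                                    none
5     covered days (carry-over within OW) / first to last event    within OW
6     covered days (carry-over within OW) / first event to OW end  within OW
7     covered days / OW start to OW end                            into + within
8     as CMA7, OW start lagged past the carried-in supply          into + within
9     OW days weighted by per-interval supply ratios / OW days     into + within
====  ==========================================================  ==========

CMA1/2 can exceed 100% (the classical medication possession ratio, MPR);
CMA3-9 are proportions of days covered (PDC) and never exceed 100%.
All spans are half-open day counts; values are exact rationals until the
final division.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import pandas as pd

from .coverage_engine import (CarryoverPolicy, Event, build_coverage,
                              events_from_frame, interval_supply_ratios, _Sweep)
from .event_store import EventTable
from .windows import ResolvedWindow, WindowSpec, resolve_window

__all__ = ["CmaPolicy", "CmaResult", "compute_simple_cma", "cma_for_patient",
           "results_to_frame", "round_percent"]


def round_percent(x: float | None) -> float | None:
    """Display rounding: half-up to one decimal of a percent."""
    if x is None:
        return None
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass(frozen=True)
class CmaPolicy:
    """Which CMA variant to compute, and its carry-over options.

    Carry-over flags are meaningful from CMA5 upward; ``carryover_into_ow``
    is implied for CMA7-9 regardless of the flag.  CMA1-4 ignore the policy.
    """

    variant: int = 7
    carryover: CarryoverPolicy = field(default_factory=CarryoverPolicy)

    def __post_init__(self) -> None:
        if self.variant not in range(1, 10):
            raise ValueError(f"CMA variant must be 1..9, got {self.variant}")

    @property
    def effective_carryover(self) -> CarryoverPolicy:
        if self.variant >= 7 and not self.carryover.carryover_into_ow:
            return replace(self.carryover, carryover_into_ow=True)
        return self.carryover


@dataclass(frozen=True)
class CmaResult:
    """One CMA estimate with its full provenance.

    ``value`` is a percentage (may exceed 100 for CMA1/2) or ``None`` when the
    estimate is undefined for this patient/window (see ``reason``).
    ``numerator``/``denominator`` are day counts (a weighted day sum for
    CMA9); for CMA8 the ``lag_days`` consumed by carried-in supply shorten
    both.
    """

    patient_id: object
    variant: int
    value: float | None
    numerator: float
    denominator: float
    ow_start: date
    ow_end: date
    lag_days: float = 0.0
    reason: str | None = None
    policy: CmaPolicy | None = None

    @property
    def value_rounded(self) -> float | None:
        return round_percent(self.value)


def _result(pid, policy, win, num, den, lag=Fraction(0), reason=None):
    value = None if (reason or den == 0) else float(100 * Fraction(num) / Fraction(den))
    return CmaResult(
        patient_id=pid, variant=policy.variant, value=value,
        numerator=float(num), denominator=float(den),
        ow_start=win.ow_start, ow_end=win.ow_end, lag_days=float(lag),
        reason=reason or (None if den != 0 else "zero-length evaluation span"),
        policy=policy,
    )


def cma_for_patient(pid, events: list[Event], win: ResolvedWindow,
                    policy: CmaPolicy, *, require_event_in_ow: bool = True
                    ) -> CmaResult:
    """Compute one simple CMA for one patient's (sorted) events.

    ``require_event_in_ow=False`` is used by sliding-window evaluation: an
    eventless window yields 0% for the coverage-based variants over fixed
    denominators (7 and 9) and a flagged empty result for variants anchored
    on in-window events (1-6).
    """
    v, co = policy.variant, policy.effective_carryover
    fuw_a, fuw_b = win.fuw_start.toordinal(), win.fuw_end.toordinal()
    ow_a, ow_b = win.ow_start.toordinal(), win.ow_end.toordinal()
    fuw_events = [e for e in events if fuw_a <= e.t < fuw_b]
    in_ow = [e for e in fuw_events if ow_a <= e.t < ow_b]

    if not in_ow and (require_event_in_ow or v in (1, 2, 3, 4, 5, 6)):
        return _result(pid, policy, win, 0, win.ow_days,
                       reason="no medication event in the observation window")

    if v in (1, 3):
        num = sum(e.duration for e in in_ow[:-1])
        den = in_ow[-1].t - in_ow[0].t
        if den == 0:
            return _result(pid, policy, win, num, 0,
                           reason="CMA%d needs two distinct event dates in the OW" % v)
        r = _result(pid, policy, win, num, den)
        if v == 3 and r.value is not None and r.value > 100:
            r = replace(r, value=100.0)
        return r
    if v in (2, 4):
        num = sum(e.duration for e in in_ow)
        den = ow_b - in_ow[0].t
        r = _result(pid, policy, win, num, den)
        if v == 4 and r.value is not None and r.value > 100:
            r = replace(r, value=100.0)
        return r
    if v in (5, 6):
        span_b = in_ow[-1].t if v == 5 else ow_b
        span_a = in_ow[0].t
        if span_b == span_a:
            return _result(pid, policy, win, 0, 0,
                           reason="CMA5 needs two distinct event dates in the OW")
        tl = build_coverage(in_ow, span_a, span_b, co)
        return _result(pid, policy, win, tl.covered_days_in(span_a, span_b),
                       span_b - span_a)
    if v == 7:
        contributing = [e for e in fuw_events if e.t < ow_b]
        tl = build_coverage(contributing, ow_a, ow_b, co)
        return _result(pid, policy, win, tl.covered_days_in(ow_a, ow_b),
                       ow_b - ow_a)
    if v == 8:
        pre = [e for e in fuw_events if e.t < ow_a]
        sweep = _Sweep(co)
        pre_end = Fraction(ow_a)
        for e in pre:
            pre_end = sweep.feed(e)
        lag = min(max(Fraction(0), pre_end - ow_a), Fraction(ow_b - ow_a))
        contributing = [e for e in fuw_events if e.t < ow_b]
        tl = build_coverage(contributing, ow_a, ow_b, co)
        lagged_a = Fraction(ow_a) + lag
        den = Fraction(ow_b) - lagged_a
        if den == 0:
            return _result(pid, policy, win, 0, 0, lag=lag,
                           reason="carried-in supply covers the entire OW")
        return _result(pid, policy, win, tl.covered_days_in(lagged_a, ow_b),
                       den, lag=lag)
    # v == 9
    tl = interval_supply_ratios(fuw_events, fuw_a, fuw_b, co)
    return _result(pid, policy, win, tl.ratio_weight_in(ow_a, ow_b), ow_b - ow_a)


def compute_simple_cma(events: EventTable, window_spec: WindowSpec,
                       policy: CmaPolicy) -> list[CmaResult]:
    """One :class:`CmaResult` per patient (patients without events in their
    OW yield a flagged empty result, with a warning)."""
    out = []
    for pid in events.patient_ids:
        evs = events_from_frame(events.for_patient(pid))
        win = resolve_window(window_spec, evs[0].date if evs else None)
        res = cma_for_patient(pid, evs, win, policy)
        if res.reason is not None:
            warnings.warn(f"patient {pid!r}: {res.reason}")
        out.append(res)
    return out


def results_to_frame(results: list[CmaResult]) -> pd.DataFrame:
    """Per-patient delimited-friendly table (value rounded to 0.1%)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "variant": r.variant,
                "value_percent": r.value_rounded,
                "numerator_days": r.numerator,
                "denominator_days": r.denominator,
                "ow_start": r.ow_start.isoformat(),
                "ow_end": r.ow_end.isoformat(),
                "lag_days": r.lag_days,
                "note": r.reason or "",
            }
            for r in results
        ]
    )
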