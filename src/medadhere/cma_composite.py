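"""Per-episode and sliding-window CMA evaluation.

Adherence (implementation) is only meaningful during persistent use, so the
simple CMAs can be evaluated inside each detected treatment episode
(``cma_per_episode``); alternatively, evaluating them in fixed-size sliding
windows (``cma_sliding_window``) relaxes the abrupt persistent/discontinued
dichotomy: windows that fall entirely inside a long supply gap score 0%,
windows overlapping an episode's tail show a gradual decline.

Windowing semantics:

* each treatment episode (its start to its reported end date, which for a
  final still-persistent episode extends to the FUW end) serves as *both*
  FUW and OW of a standalone simple-CMA evaluation over the episode's own
  events — no supply is carried in from before the episode, and CMA9's
  interval ratios are episode-local;
* each sliding window is the OW of a simple-CMA evaluation inside the global
  FUW: carry-in for CMA7-9 flows from all earlier events, and CMA9's ratios
  are computed once over the whole FUW.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .cma_engine import CmaPolicy, CmaResult, cma_for_patient
from .coverage_engine import events_from_frame
from .episodes import EpisodePolicy, _patient_episodes
from .event_store import EventTable
from .windows import Duration, ResolvedWindow, WindowSpec, _as_duration, resolve_window

__all__ = ["SlidingSpec", "CompositeResult", "cma_per_episode",
           "cma_sliding_window", "composite_to_frame"]


@dataclass(frozen=True)
class SlidingSpec:
    """Sliding-window generation: start offset from the OW start, window
    duration, and either a fixed step or a target number of windows.

    With ``n_windows`` given, the step is ``(OW length - duration) / (n - 1)``
    floored to whole days (``n == 1`` places a single window at the OW
    start).  Windows are clipped to the OW; a trailing partial window is
    emitted and flagged rather than dropped.
    """

    start_offset: object = 0
    window_duration: object = 365
    step: object | None = None
    n_windows: int | None = None

    def __post_init__(self) -> None:
        if (self.step is None) == (self.n_windows is None):
            raise ValueError("give exactly one of step or n_windows")
        if self.n_windows is not None and self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")

    def windows(self, ow_start: date, ow_end: date) -> list[tuple[date, date, bool]]:
        """Concrete (start, end, is_partial) windows within ``[ow_start, ow_end)``."""
        dur = _as_duration(self.window_duration)
        start = _as_duration(self.start_offset).add_to(ow_start)
        if dur.add_to(ow_start) <= ow_start:
            raise ValueError("window_duration must be positive")
        if self.step is not None:
            step = _as_duration(self.step)
            if step.add_to(ow_start) <= ow_start:
                raise ValueError("step must be positive")
        else:
            if self.n_windows == 1:
                step = Duration((ow_end - start).days, "days")  # single window
            else:
                span = (ow_end - start).days - (dur.add_to(start) - start).days
                step = Duration(max(1, span // (self.n_windows - 1)), "days")
        out = []
        s = start
        while s < ow_end:
            full_end = dur.add_to(s)
            e = min(full_end, ow_end)
            out.append((s, e, e < full_end))
            if self.n_windows is not None and len(out) == self.n_windows:
                break
            s = step.add_to(s)
        return out


@dataclass(frozen=True)
class CompositeResult:
    """One (patient, episode-or-window) CMA estimate."""

    patient_id: object
    unit_index: int  # 1-based
    unit_start: date
    unit_end: date
    cma: CmaResult
    partial: bool = False  # trailing sliding window clipped short


def cma_per_episode(events: EventTable, window_spec: WindowSpec,
                    episode_policy: EpisodePolicy, cma_policy: CmaPolicy
                    ) -> list[CompositeResult]:
    """Detect treatment episodes, then evaluate the chosen simple CMA inside
    each episode (the episode interval acting as FUW = OW)."""
    out: list[CompositeResult] = []
    for pid in events.patient_ids:
        evs = events_from_frame(events.for_patient(pid))
        win = resolve_window(window_spec, evs[0].date if evs else None)
        recs = _patient_episodes(pid, evs, win.fuw_start.toordinal(),
                                 win.fuw_end.toordinal(), episode_policy)
        for rec in recs:
            ep_win = ResolvedWindow(rec.start_date, rec.end_date,
                                    rec.start_date, rec.end_date)
            a, b = rec.start_date.toordinal(), rec.end_date.toordinal()
            ep_events = [e for e in evs if a <= e.t < b]
            res = cma_for_patient(pid, ep_events, ep_win, cma_policy)
            out.append(CompositeResult(pid, rec.episode_index, rec.start_date,
                                       rec.end_date, res))
    return out


def cma_sliding_window(events: EventTable, window_spec: WindowSpec,
                       sliding_spec: SlidingSpec, cma_policy: CmaPolicy
                       ) -> list[CompositeResult]:
    """Evaluate the chosen simple CMA in each generated sliding window.

    Windows without events yield 0% for CMA7/9 (fixed-denominator coverage
    measures) and a flagged empty result for the event-anchored CMA1-6.
    """
    out: list[CompositeResult] = []
    for pid in events.patient_ids:
        evs = events_from_frame(events.for_patient(pid))
        win = resolve_window(window_spec, evs[0].date if evs else None)
        for k, (ws, we, partial) in enumerate(
                sliding_spec.windows(win.ow_start, win.ow_end), start=1):
            res = cma_for_patient(pid, evs, win.with_ow(ws, we), cma_policy,
                                  require_event_in_ow=False)
            out.append(CompositeResult(pid, k, ws, we, res, partial=partial))
    return out


def composite_to_frame(results: list[CompositeResult]) -> pd.DataFrame:
    """Long-format table: one row per (patient, episode/window)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "unit_index": r.unit_index,
                "unit_start": r.unit_start.isoformat(),
                "unit_end": r.unit_end.isoformat(),
                "unit_days": (r.unit_end - r.unit_start).days,
                "variant": r.cma.variant,
                "value_percent": r.cma.value_rounded,
                "partial_window": r.partial,
                "note": r.cma.reason or "",
            }
            for r in results
        ]
    )
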