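"""Static plots of medication histories with episode / window CMA overlays.

One horizontal lane per patient: every medication event is a bar of length
``duration_days`` colored by category, with the FUW/OW shaded behind it.
Episode or sliding-window results stack above the history as annotated bars
(start, end, CMA value), and an optional side panel shows the distribution of
the per-patient CMA values.  Output is deterministic vector or raster
(PDF/SVG/PNG); the time axis shows calendar dates, or days since each
patient's first event when histories are aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import matplotlib
matplotlib.use("Agg")
import matplotlib.dates as mdates
import matplotlib.pyplot as plt
from matplotlib.patches import Patch

from .cma_composite import CompositeResult
from .coverage_engine import events_from_frame
from .event_store import EventTable
from .windows import WindowSpec, resolve_window

__all__ = ["PlotSpec", "plot_history"]

# colorblind-safe categorical palette (Okabe-Ito)
_PALETTE = ["#0072B2", "#D55E00", "#009E73", "#CC79A7", "#E69F00", "#56B4E9"]
_GRAYS = ["#222222", "#888888", "#555555", "#bbbbbb", "#000000", "#999999"]


@dataclass(frozen=True)
class PlotSpec:
    """What to draw and how."""

    patients: tuple = ()  # empty = all patients in the table
    show_windows: bool = True
    show_cma_panel: bool = True
    grayscale: bool = False
    align_first_event: bool = False
    figsize: tuple = (10.0, 4.0)
    dpi: int = 150


class PlotError(ValueError):
    pass


def _category_colors(categories, grayscale):
    pal = _GRAYS if grayscale else _PALETTE
    return {c: pal[i % len(pal)] for i, c in enumerate(sorted(categories))}


def plot_history(events: EventTable, results: list[CompositeResult] | None = None,
                 spec: PlotSpec | None = None, out=None,
                 window_spec: WindowSpec | None = None):
    """Render medication histories (and optional CMA overlays) to ``out``.

    ``results`` may hold per-episode or sliding-window estimates; every
    referenced patient must be selected.  Returns the matplotlib figure (also
    written to ``out`` if given; format follows the file extension).
    """
    spec = spec or PlotSpec()
    pids = list(spec.patients) or events.patient_ids
    if not pids:
        raise PlotError("empty patient selection")
    known = set(events.patient_ids)
    unknown = [p for p in pids if p not in known]
    if unknown:
        raise PlotError(f"unknown patients: {unknown}")
    results = results or []
    extra = {r.patient_id for r in results} - set(pids)
    if extra:
        raise PlotError(f"results reference unselected patients: {sorted(extra)}")

    per_patient = {pid: events_from_frame(events.for_patient(pid)) for pid in pids}
    cats = {e.category for evs in per_patient.values() for e in evs}
    colors = _category_colors(cats, spec.grayscale)

    with_panel = spec.show_cma_panel and results
    fig, axes = plt.subplots(
        1, 2 if with_panel else 1,
        width_ratios=[4, 1] if with_panel else None,
        figsize=spec.figsize, dpi=spec.dpi, squeeze=False,
    )
    ax = axes[0][0]

    def x(d: date, pid) -> float:
        if spec.align_first_event:
            return (d - per_patient[pid][0].date).days
        return mdates.date2num(d)

    lane_h, bar_h = 1.0, 0.28
    by_pid: dict[object, list[CompositeResult]] = {}
    for r in results:
        by_pid.setdefault(r.patient_id, []).append(r)

    for lane, pid in enumerate(pids):
        evs = per_patient[pid]
        y0 = lane * lane_h
        if spec.show_windows and window_spec is not None and evs:
            win = resolve_window(window_spec, evs[0].date)
            ax.axvspan(x(win.fuw_start, pid), x(win.fuw_end, pid),
                       ymin=0, ymax=1, color="0.93", zorder=0)
            ax.plot([x(win.ow_start, pid), x(win.ow_end, pid)],
                    [y0 - 0.38] * 2, color="0.55", lw=3, solid_capstyle="butt")
        for e in evs:
            ax.barh(y0, x(date.fromordinal(e.t + e.duration), pid) - x(e.date, pid),
                    left=x(e.date, pid), height=bar_h,
                    color=colors[e.category], edgecolor="black", lw=0.4, zorder=3)
        for j, r in enumerate(sorted(by_pid.get(pid, []), key=lambda r: r.unit_index)):
            yy = y0 + bar_h / 2 + 0.12 + 0.14
            ax.barh(yy, x(r.unit_end, pid) - x(r.unit_start, pid),
                    left=x(r.unit_start, pid), height=0.10,
                    color="0.4" if spec.grayscale else "#44AA99",
                    edgecolor="black", lw=0.3, zorder=2)
            label = ("NA" if r.cma.value is None
                     else f"{r.cma.value_rounded:.1f}%")
            ax.annotate(label, ((x(r.unit_start, pid) + x(r.unit_end, pid)) / 2,
                                yy + 0.08),
                        ha="center", va="bottom", fontsize=7, zorder=4)

    ax.set_yticks([lane * lane_h for lane in range(len(pids))])
    ax.set_yticklabels([str(p) for p in pids])
    ax.set_ylabel("patient")
    ax.set_ylim(-0.6, (len(pids) - 1) * lane_h + 0.9)
    if spec.align_first_event:
        ax.set_xlabel("days since first event")
    else:
        ax.xaxis.set_major_locator(mdates.AutoDateLocator())
        ax.xaxis.set_major_formatter(mdates.ConciseDateFormatter(ax.xaxis.get_major_locator()))
        ax.set_xlabel("date")
    ax.legend(handles=[Patch(facecolor=c, edgecolor="black", label=k)
                       for k, c in colors.items()],
              loc="upper left", fontsize=7, frameon=False)

    if with_panel:
        axp = axes[0][1]
        vals = [r.cma.value_rounded for r in results if r.cma.value is not None]
        axp.hist(vals, bins=10, color="0.6", edgecolor="black")
        axp.set_xlabel("CMA (%)")
        axp.set_ylabel("episodes / windows")
    fig.tight_layout()

    if out is not None:
        fig.savefig(out, metadata=_stable_metadata(str(out)))
    return fig


def _stable_metadata(path: str) -> dict:
    # pin timestamps so identical inputs give byte-stable vector output
    if path.endswith(".svg"):
        return {"Date": "1970-01-01"}
    if path.endswith(".pdf"):
        return {"CreationDate": None}
    return {}
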