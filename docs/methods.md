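# Methods

## Data model and conventions

A medication event is `(patient_id, event_date, daily_dose, category,
duration_days)`: `duration_days` is the number of days the supplied quantity
lasts at the recommended daily dose (optionally derived as
`floor(quantity / daily_dose)` through a reader hook; no rounding rule is
standard, so we floor). `daily_dose` and `category` are optional; options
that need them (dose-aware conversion, category-restricted carry-over,
episode splitting on medication change) refuse tables where they are absent.
Dates carry no time-of-day; the date dialect of an input file is explicit
configuration, never inferred. Duplicate rows are legitimate dispensations
and retained; same-date events are processed in input order, their supplies
queueing sequentially.

**Interval convention.** Every window, episode and covered interval is
half-open `[start, end)` on the integer day axis; reported "end dates" are
the exclusive bound, so `duration = end − start` holds exactly, including
across leap years (a 730-day window starting 2035-12-13 ends 2037-12-12
because 2036 is a leap year). Day/week offsets add exact day counts;
month/year offsets use calendar arithmetic with end-of-month clamping. The
reference computations in the test suite and acceptance script use
day-count durations throughout (730/365-day windows, a 182-day offset for
the interior "months 6–18" window): day counts are the only convention that
reproduces the reference example values across the leap year, and we treat
them as the definition of those scenarios.

## The carry-over engine

The supply model assumes supplied = used at the recommended rate. A
sequential sweep maintains the active supply's exhaustion point: each event
deposits `duration_days` beginning at `max(event date, current exhaustion)`
(supply cannot cover the past). Options:

* **No carry-over**: a new event discards whatever supply remained
  (truncation, the usual dispensing-data convention) — so coverage is the
  run of each event's own supply until the next event.
* **Carry-over within the window** (default): surplus days queue behind the
  new supply.
* **Dose-aware conversion**: surplus is converted through the pill count,
  `surplus_days × old_dose / new_dose`, at the moment of the new event, and
  coverage beyond that date is re-deposited at the new rate (a dose increase
  shrinks the remaining coverage). Converted amounts are exact
  `fractions.Fraction`s; nothing is rounded until reporting.
* **Same-medication-only**: when the category changes while supply remains,
  consumption switches to the new medication and the old category's surplus
  is *frozen* — it stops covering days but is not destroyed, resuming only
  at a later event of that category (within one sweep; treatment-episode
  detection resets all supply state at each episode start, since a
  discontinuation ends the ledger). Frozen amounts are reported separately
  so that total deposited supply = covered + residual + frozen.

The engine is verified against an independently written brute-force oracle —
a literal day-by-day pill-stock simulation with a per-category remaining-
supply ledger — with exact equality on 1,000 random histories (≤ 20 events,
≤ 800 days) under every policy combination.

## Episode detection

Events are swept chronologically; the time from the governing supply's
exhaustion to the next event is compared against the permissible gap
(days/weeks/months/years, or percent of the most recent event's duration —
the natural reading of an event-scoped "percent of duration"). A gap
violation, or (if enabled) a category change, closes the episode at
`min(exhaustion, next event date)`: a medication change during still-active
supply ends the old episode exactly at the changing event, and change takes
precedence over the gap rule when both coincide. The final episode extends
to the FUW end when its trailing gap is within the permissible gap,
otherwise it ends at exhaustion; the trailing gap (to the next episode or
the FUW end) is always reported. These rules yield the chaining identity
`end + trailing gap = next start` for gap-closed episodes.

## The nine CMA estimators

See the README table for definitions. Numerical choices worth recording:

* "Last event" for CMA1/3/5 is the chronologically last event dated inside
  the OW; its duration is excluded from the CMA1/3 numerator, and the CMA5
  span ends at its date. With a single in-OW event these spans are
  degenerate and the estimate is a flagged missing value, not 100%.
* Events dated before the OW are invisible to CMA1–6 and enter CMA7–9 only
  through carried-in supply. An event *dated* inside the OW contributes its
  full recorded duration to the CMA1–4 numerators even if the supply runs
  past the OW end (the classical MPR overcount those variants exist to
  expose).
* The CMA8 lag is the number of OW days consumed by supply carried from
  before the OW start (12 days in the packaged example's interior window);
  both numerator window and denominator shrink by it. A window fully
  pre-covered yields a flagged missing value (0/0).
* CMA9's interval ratios are computed once over the whole FUW, even when
  the OW is interior; days before the first event have ratio 0. Because the
  ratio spreads supply to the *next event*, a window inside a long gap
  retains the diluted ratio rather than dropping to 0% — only CMA7 is a
  strict interruption detector.
* Display rounding is half-up to one decimal of a percent; all comparisons
  in tests allow ±0.05 percentage points to absorb printing.

**Per-episode evaluation** treats each detected episode interval (start to
reported end, i.e. gap-extended to the FUW end for a final still-persistent
episode) as both FUW and OW of a standalone evaluation over the episode's
own events: no supply crosses an episode boundary, and CMA9's ratios are
episode-local. **Sliding windows**, by contrast, keep the global FUW:
carry-in flows from all earlier events and CMA9's ratios are FUW-wide. When
a window count is given instead of a step, the step is
`(OW length − duration) / (n − 1)` floored to whole days; a trailing partial
window is emitted and flagged rather than dropped, keeping the tiling
exhaustive.

## Synthetic cohorts

`generate_synthetic_cohort` emulates the marginal structure of a dispensing
database: ~10.8 events per patient (Poisson, min 1) inside a personal
2-year span; daily doses on {2..20} with median 4; durations on {20..150}
days with median 50; two categories near 50/50 with occasional switching
(8% per event); inter-refill intervals are the previous duration scaled by
a lognormal factor (σ = 0.35, slight late bias), producing both stockpiling
and gaps. These values are the documented study conditions; only marginals
are meaningful. What the generator does *not* emulate — dose titration
trajectories, seasonal refill patterns, censoring by death or
hospitalization, multi-pharmacy duplication — bounds what passing tests say
about real data: they validate the computational contract, not clinical
realism.

## Performance and parallelism

The engine is event-interval based (not day-resolution), so cost scales
with events, not window length. Per-patient computations are pure; the CLI
partitions patients across joblib workers deterministically and reassembles
results in input order, making multi-worker output row-identical to serial
output.

## Known limitations

Single data source; no initiation (time-to-first-fill) measure, no
hospitalization or prescription-pattern adjustment, no combined
multi-medication indices, and no automatic disambiguation of therapy
switches versus concomitant use — category-restricted carry-over and
episode splitting are the available levers, and corrections from auxiliary
data must be applied to the input table. Whether a frozen other-category
surplus should eventually expire within an episode is not empirically
settled; it persists here, and sensitivity analyses can toggle
`same_medication_only` to bound the effect.
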