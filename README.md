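# medadhere

Adherence and persistence estimation from electronic healthcare data
(prescribing or dispensing records), with publication-quality plotting of
individual medication histories.

## The problem

Routinely collected medication records — one row per prescription or
dispensation, with a patient id, a date, and the number of days the supplied
quantity lasts — are the cheapest large-scale window onto how patients
actually use long-term medication. Two distinct quantities are usually
estimated from them:

* **Persistence** — how long a patient keeps using the therapy, formalized as
  *treatment episodes*: maximal runs of events in which the interruption
  between the end of one event's supply and the next event never exceeds a
  researcher-chosen *permissible gap*.
* **Adherence (implementation)** — during use, what fraction of time the
  patient had medication available, as a *continuous multiple-interval
  measure of medication availability* (CMA): a ratio of supplied (or covered)
  time to evaluated time.

The literature hides many non-equivalent operationalizations behind labels
like MPR (medication possession ratio) and PDC (proportion of days covered).
`medadhere` implements nine explicitly defined CMA variants that differ along
four axes: how the evaluated span is anchored; whether the ratio is capped at
100%; whether *oversupply carries over* between refills (optionally only
within the same medication category, and optionally converted through pill
counts when the daily dose changes, `surplus_days × old_dose / new_dose`);
and whether supply acquired before the observation window is credited.

With a follow-up window (FUW) per patient and an observation window (OW)
inside it, the variants are:

| CMA | numerator / denominator | carry-over |
|-----|-------------------------|------------|
| 1 | Σ durations excluding the last OW event / first→last OW event | none |
| 2 | Σ all OW durations / first OW event→OW end | none |
| 3, 4 | CMA1, CMA2 capped at 100% | none |
| 5 | covered days / first→last OW event | within OW |
| 6 | covered days / first OW event→OW end | within OW |
| 7 | covered days / OW start→OW end | into + within OW |
| 8 | as CMA7 with the OW start lagged past the carried-in supply | into + within OW |
| 9 | OW days weighted by per-interval supply ratios / OW days | into + within OW |

CMA1/2 can exceed 100% (MPR-style); CMA3–9 cannot (PDC-style). CMA9 first
spreads each event's supply evenly over the interval to the next event
(ratio capped at 1, oversupply carried forward), then averages the per-day
ratios over the OW — making repeated estimates insensitive to where the OW
boundary falls between refills.

Every estimator can be evaluated over one OW per patient (*simple*), inside
each detected treatment episode (*per episode*), or in fixed-size sliding
windows (*sliding*), and all computations use exact rational arithmetic on
half-open day intervals (reported end dates are exclusive bounds, so
`duration = end − start` even across leap years).

## Worked example

Treatment episodes for the packaged example patients, with a 90-day
permissible gap and same-medication, dosage-aware carry-over over a 730-day
follow-up window:

```
$ medadhere episodes --input fixture --gap 90 --fuw-duration "730 days" \
    --same-medication-only --consider-dosage-change
patient_id,episode_number,episode_start,gap_days,episode_duration,episode_end
37,1,2036-04-10,122,608,2037-12-09
76,1,2035-12-13,144,434,2037-02-19
76,2,2037-07-13,32,152,2037-12-12
```

Patient 37 stays in one 608-day episode (their longest refill interruption,
67 days, is under the gap limit) that ends when the last event's supply runs
out, 122 days before the window closes. Patient 76 discontinues after 434
days, restarts 144 days later, and is still covered within the permissible
gap when the window ends. CMA7 (proportion of days covered, with carry-over
into and within the window) over an interior 1-year OW starting 182 days
into the follow-up:

```
$ medadhere cma --input fixture --variant 7 --fuw-duration "730 days" \
    --ow-offset "182 days" --ow-duration "365 days"
patient_id,variant,value_percent,numerator_days,denominator_days,ow_start,ow_end,lag_days,note
37,7,40.8,149.0,365.0,2036-10-09,2037-10-09,0.0,
76,7,69.0,252.0,365.0,2036-06-12,2037-06-12,0.0,
```

Patient 76 had medication available 252 of 365 days (69.0%): 12 days carried
in from a refill before the window plus 240 contiguous covered days. The
same library calls are available in Python (`compute_treatment_episodes`,
`compute_simple_cma`, `cma_per_episode`, `cma_sliding_window`,
`plot_history`), and `medadhere simulate` generates seeded synthetic cohorts
for method exploration.

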