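"""Independent brute-force oracle: a day-by-day pill-stock simulation.

Deliberately written without reference to the interval engine: it walks the
calendar one day at a time, keeping a per-medication remaining-supply ledger
(exact rationals), consuming one day of supply per day from the medication
most recently supplied.  Used to cross-check the engine's covered-day totals
on random event histories.
"""

from fractions import Fraction

import numpy as np

from medadhere import CarryoverPolicy, Event


def daily_stock_covered(events: list[Event], start: int, end: int,
                        policy: CarryoverPolicy) -> Fraction:
    """Total covered time (possibly fractional days) within [start, end)."""
    if not policy.carryover_within_ow:
        # no carry-over: each new event discards remaining supply, so a day is
        # covered iff the most recent event's own supply is still running
        covered = 0
        for day in range(start, end):
            latest = [e for e in events if e.t <= day]
            if latest and day < latest[-1].t + latest[-1].duration:
                covered += 1
        return Fraction(covered)

    by_day: dict[int, list[Event]] = {}
    for e in events:
        by_day.setdefault(e.t, []).append(e)
    first = min(by_day) if by_day else start
    pools: dict[str, list] = {}  # key -> [remaining_days, dose]
    active: str | None = None
    covered = Fraction(0)
    for day in range(min(first, start), end):
        for e in by_day.get(day, ()):
            k = e.category if policy.same_medication_only else ""
            pool = pools.setdefault(k, [Fraction(0), e.dose])
            if (policy.consider_dosage_change and pool[0] > 0
                    and pool[1] is not None and e.dose is not None
                    and pool[1] != e.dose):
                pool[0] = pool[0] * pool[1] / e.dose
            pool[0] += e.duration
            pool[1] = e.dose
            active = k
        if active is not None and pools.get(active, [0])[0] > 0:
            take = min(Fraction(1), pools[active][0])
            pools[active][0] -= take
            if day >= start:
                covered += take
    return covered


def random_patient(rng: np.random.Generator, max_events: int = 20,
                   horizon: int = 800, base: int = 0) -> list[Event]:
    """A random medication history on the integer day axis [base, base+horizon)."""
    n = int(rng.integers(1, max_events + 1))
    days = np.sort(rng.integers(0, horizon, size=n))
    evs = [
        Event(
            t=base + int(t),
            duration=int(rng.integers(1, 91)),
            dose=Fraction(int(rng.integers(1, 6))),
            category=str(rng.choice(["medA", "medB"])),
        )
        for t in days
    ]
    return evs
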