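"""Reading, validating and generating medication-event tables.

A medication event is one prescribing or dispensing record: a patient
identifier, an event date, a daily dose (doses/day the supply is meant to be
taken at), a free-text medication category, and a duration in days that the
supplied quantity lasts when used as recommended.  Tables of such events are
the sole input of every estimator in this package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical internal column names
COLUMNS = ["patient_id", "event_date", "daily_dose", "category", "duration_days"]

#: default column names of the delimited input format
DEFAULT_COLUMN_MAP = {
    "patient_id": "PATIENT_ID",
    "event_date": "DATE",
    "daily_dose": "PERDAY",
    "category": "CATEGORY",
    "duration_days": "DURATION",
}

REQUIRED = ("patient_id", "event_date", "duration_days")


class EventValidationError(ValueError):
    """Input rows violate the event-table contract; message lists the rows."""


class EmptyInputError(ValueError):
    """The input file contains a header but no data rows."""


class ConfigurationError(ValueError):
    """The reader configuration does not match the file (missing columns...)."""


@dataclass
class EventTable:
    """An ordered collection of medication events.

    ``data`` holds one row per event with the canonical columns
    (:data:`COLUMNS`); ``event_date`` is ``datetime64[ns]`` (dates only,
    midnight).  Row order is the stable sort key (patient, date, input order).
    Duplicate rows are legitimate (two identical dispensations) and retained.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"event table lacks columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> list:
        return list(pd.unique(self.data["patient_id"]))

    def for_patient(self, patient_id) -> pd.DataFrame:
        """Events of one patient, sorted by (date, original input order)."""
        sub = self.data[self.data["patient_id"] == patient_id]
        return sub.sort_values("event_date", kind="stable").reset_index(drop=True)

    def sorted(self) -> pd.DataFrame:
        return self.data.sort_values(
            ["patient_id", "event_date"], kind="stable"
        ).reset_index(drop=True)

    def write(self, path, *, sep: str = ",", date_format: str = "%Y-%m-%d",
              column_map: dict | None = None) -> None:
        """Write as delimited text; ISO dates by default (round-trips exactly)."""
        cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
        out = self.data.copy()
        out["event_date"] = out["event_date"].dt.strftime(date_format)
        out = out.rename(columns=cmap)[[cmap[c] for c in COLUMNS]]
        out.to_csv(path, sep=sep, index=False)


def _validate(df: pd.DataFrame, *, context: str) -> pd.DataFrame:
    bad: list[str] = []
    if df["patient_id"].isna().any():
        rows = df.index[df["patient_id"].isna()].tolist()
        bad.append(f"missing patient_id in rows {rows}")
    if df["event_date"].isna().any():
        rows = df.index[df["event_date"].isna()].tolist()
        bad.append(f"unparseable event date in rows {rows}")
    dur = pd.to_numeric(df["duration_days"], errors="coerce")
    baddur = df.index[~(dur >= 1) | (dur != dur.round())].tolist()
    if baddur:
        bad.append(f"duration_days must be a whole number >= 1; offending rows {baddur}")
    dose = pd.to_numeric(df["daily_dose"], errors="coerce")
    # daily dose is optional (may be all-NaN) but where present must be > 0
    baddose = df.index[dose.notna() & ~(dose > 0)].tolist()
    if baddose:
        bad.append(f"daily_dose must be > 0 where given; offending rows {baddose}")
    if bad:
        raise EventValidationError(f"{context}: " + "; ".join(bad))
    out = df.copy()
    out["duration_days"] = dur.astype(int)
    out["daily_dose"] = dose
    return out


def read_events(path, *, date_format: str = "%m/%d/%Y", sep: str = ",",
                column_map: dict | None = None,
                quantity_column: str | None = None) -> EventTable:
    """Read a delimited event table.

    Parameters
    ----------
    path:
        File path (or readable buffer) of a delimited text file with a header.
    date_format:
        Explicit ``strftime`` dialect for the date column.  Never inferred:
        month/day ambiguity must be resolved by the caller.
    sep:
        Field delimiter (``","`` or ``"\\t"``).
    column_map:
        Mapping from canonical names (:data:`COLUMNS`) to file column names;
        defaults to PATIENT_ID/DATE/PERDAY/CATEGORY/DURATION.
    quantity_column:
        Optional pre-processing hook: if given, duration is derived as
        ``floor(quantity / daily_dose)`` from this column instead of being
        read directly.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    need = [cmap[c] for c in ("patient_id", "event_date")]
    if quantity_column is None:
        need.append(cmap["duration_days"])
    else:
        need += [quantity_column, cmap["daily_dose"]]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing columns {missing}")

    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw[cmap["patient_id"]]
    df["event_date"] = pd.to_datetime(
        raw[cmap["event_date"]], format=date_format, errors="coerce"
    )
    dose_col = cmap.get("daily_dose")
    df["daily_dose"] = (
        pd.to_numeric(raw[dose_col], errors="coerce")
        if dose_col in raw.columns else np.nan
    )
    cat_col = cmap.get("category")
    df["category"] = raw[cat_col] if cat_col in raw.columns else ""
    if quantity_column is not None:
        qty = pd.to_numeric(raw[quantity_column], errors="coerce")
        df["duration_days"] = np.floor(qty / df["daily_dose"])
    else:
        df["duration_days"] = pd.to_numeric(
            raw[cmap["duration_days"]], errors="coerce"
        )
    df = _validate(df, context=str(path))
    return EventTable(df[COLUMNS], provenance=str(path))


def fixture_two_patients() -> EventTable:
    """The packaged 19-event, two-patient example table.

    Patient 37 has 8 events (constant daily dose, duration changes with a
    medication switch); patient 76 has 11 events with three dose changes and
    two duration changes.  All worked examples in the documentation and the
    acceptance checks derive from these two histories.
    """
    ref = resources.files("medadhere").joinpath("_data/two_patients.csv")
    with ref.open("rb") as fh:
        table = read_events(io.BytesIO(fh.read()), date_format="%m/%d/%Y")
    table.provenance = "packaged fixture: two example patients"
    return table


# marginal distributions of the synthetic cohort; chosen so that the median
# daily dose is 4 (range 2-20) and the median duration 50 days (range 20-150),
# with two medication categories in roughly equal proportion
_DOSES = np.array([2, 3, 4, 6, 8, 10, 12, 16, 20])
_DOSE_W = np.array([0.18, 0.17, 0.30, 0.12, 0.09, 0.06, 0.04, 0.02, 0.02])
_DURATIONS = np.array([20, 30, 40, 50, 60, 90, 100, 120, 150])
_DURATION_W = np.array([0.08, 0.14, 0.08, 0.30, 0.15, 0.10, 0.06, 0.05, 0.04])
_CATEGORIES = ("medA", "medB")


@dataclass
class CohortMarginals:
    """Distribution spec for :func:`generate_synthetic_cohort`."""

    doses: np.ndarray = field(default_factory=lambda: _DOSES.copy())
    dose_weights: np.ndarray = field(default_factory=lambda: _DOSE_W.copy())
    durations: np.ndarray = field(default_factory=lambda: _DURATIONS.copy())
    duration_weights: np.ndarray = field(default_factory=lambda: _DURATION_W.copy())
    categories: tuple = _CATEGORIES
    category_prob: float = 0.5
    mean_events_per_patient: float = 10.8

    def validate(self) -> None:
        for name, vals, w in (
            ("dose", self.doses, self.dose_weights),
            ("duration", self.durations, self.duration_weights),
        ):
            if len(vals) != len(w) or not np.isclose(np.sum(w), 1.0):
                raise ValueError(f"invalid {name} distribution spec")
        if not 0 < self.category_prob < 1:
            raise ValueError("category_prob must be in (0, 1)")
        if self.mean_events_per_patient < 1:
            raise ValueError("mean_events_per_patient must be >= 1")


def generate_synthetic_cohort(
    n_patients: int = 100,
    span_days: int = 730,
    seed: int = 0,
    marginals: CohortMarginals | None = None,
    start: date = date(2030, 1, 1),
) -> EventTable:
    """Generate a reproducible cohort of medication events.

    Emulates the marginal structure of a dispensing database: each patient has
    at least one event inside a personal follow-up span of ``span_days``;
    inter-event intervals hover around the previous duration (under- and
    over-supply both occur), producing realistic refill patterns with gaps and
    stockpiling.  Only marginals are meaningful; individual histories are
    random.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    m = marginals or CohortMarginals()
    m.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        pid = f"P{i + 1:04d}"
        n_events = max(1, rng.poisson(m.mean_events_per_patient))
        cat = m.categories[rng.random() > m.category_prob]
        t0 = int(rng.integers(0, max(1, span_days // 8)))
        t = t0
        for _ in range(n_events):
            if t >= t0 + span_days or t >= span_days:
                break
            dose = int(rng.choice(m.doses, p=m.dose_weights))
            dur = int(rng.choice(m.durations, p=m.duration_weights))
            rows.append((pid, start + pd.Timedelta(days=t).to_pytimedelta(), dose, cat, dur))
            if rng.random() < 0.08:  # occasional medication switch
                cat = m.categories[rng.random() > m.category_prob]
            # next refill: early (stockpiling), on time, or late (gap)
            t += max(1, int(round(dur * rng.lognormal(mean=0.05, sigma=0.35))))
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["event_date"] = pd.to_datetime(df["event_date"])
    df["daily_dose"] = df["daily_dose"].astype(float)
    df = _validate(df, context="synthetic cohort")
    return EventTable(
        df[COLUMNS], provenance=f"synthetic cohort(n={n_patients}, seed={seed})"
    )


def export_fixture(path, *, sep: str = ",") -> None:
    """Write the packaged two-patient fixture to ``path`` (ISO dates)."""
    fixture_two_patients().write(path, sep=sep)
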