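"""Data model and I/O for instantaneous scan-sampling datasets.

The observational unit is a *scan*: at a fixed interval (typically 10 min)
the observer records the focal animal's activity and the identity of every
group member within 5 m of it.  A dataset couples a table of scans with a
roster describing each individual — sex, birth date (or an explicit
adulthood date when the birth date is unknown) and group-residency spells.

CSV schemas
-----------
``scans.csv``
    ``date`` (YYYY-MM-DD), ``scan_time`` (HH:MM, optional), ``group_id``,
    ``focal_id``, ``focal_activity`` (feeding | resting | travelling |
    other | unknown), ``neighbours_5m`` (semicolon-separated IDs, empty
    allowed).
``roster.csv``
    ``id``, ``sex`` (F/M), ``birth_date`` (optional), ``adult_from``
    (optional; required when ``birth_date`` is empty), ``group_id``,
    ``entry_date``, ``exit_date`` (empty = still resident),
    ``is_potential_alpha`` (0/1).  One row per residency spell.
``alpha_schedule.csv``
    ``group_id``, ``start_date``, ``end_date`` (empty = open),
    ``alpha_id``.

All dates are naive calendar dates; ``scan_time`` is retained as metadata
only.  Females are treated as adult from the day they turn 10 years old
(inclusive boundary).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

ADULT_AGE_YEARS = 10
ACTIVITIES = ("feeding", "resting", "travelling", "other", "unknown")

SCAN_COLUMNS = ("date", "scan_time", "group_id", "focal_id",
                "focal_activity", "neighbours_5m")
ROSTER_COLUMNS = ("id", "sex", "birth_date", "adult_from", "group_id",
                  "entry_date", "exit_date", "is_potential_alpha")


class SchemaError(ValueError):
    """A CSV input is missing required columns or has malformed values."""


class ValidationError(ValueError):
    """One or more rows violate the scan-table invariants."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "; ".join(self.errors[:5])
        more = f" (+{len(self.errors) - 5} more)" if len(self.errors) > 5 else ""
        super().__init__(f"{len(self.errors)} validation error(s): {preview}{more}")


class UnknownGroupError(KeyError):
    pass


class ConfigurationError(ValueError):
    """A schedule or configuration does not cover the data it is applied to."""


class ParameterError(ValueError):
    pass


def add_years(date: dt.date, years: int) -> dt.date:
    """Calendar-year arithmetic; Feb 29 birthdays roll to Mar 1."""
    try:
        return date.replace(year=date.year + years)
    except ValueError:
        return dt.date(date.year + years, 3, 1)


def _parse_date(value, what: str) -> dt.date | None:
    if value is None:
        return None
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, (pd.Timestamp, dt.datetime)):
        return value.date()
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None
    try:
        return dt.date.fromisoformat(s)
    except ValueError as exc:
        raise SchemaError(f"bad {what} date {value!r}") from exc


@dataclass(frozen=True)
class ScanRecord:
    """One instantaneous scan: when, where, who was focal, who was within 5 m."""

    date: dt.date
    group_id: str
    focal_id: str
    neighbours_5m: frozenset[str]
    focal_activity: str = "unknown"
    scan_time: str | None = None

    def __post_init__(self):
        if self.focal_id in self.neighbours_5m:
            raise ValidationError(
                [f"focal {self.focal_id} appears in its own neighbour list"])


@dataclass(frozen=True)
class ResidencySpell:
    group_id: str
    entry: dt.date
    exit: dt.date | None = None  # None = open-ended

    def covers(self, group_id: str, date: dt.date) -> bool:
        return (self.group_id == group_id and self.entry <= date
                and (self.exit is None or date <= self.exit))

    def overlap_days(self, start: dt.date, end: dt.date) -> int:
        """Days of residency within the half-open window [start, end)."""
        last = end - dt.timedelta(days=1)
        lo = max(self.entry, start)
        hi = last if self.exit is None else min(self.exit, last)
        return max(0, (hi - lo).days + 1)


@dataclass
class Individual:
    id: str
    sex: str  # 'F' or 'M'
    birth_date: dt.date | None = None
    adult_from: dt.date | None = None
    residency: list[ResidencySpell] = field(default_factory=list)
    is_potential_alpha: bool = False

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise SchemaError(f"individual {self.id}: sex must be F or M")
        if self.birth_date is None and self.adult_from is None:
            raise SchemaError(
                f"individual {self.id}: needs birth_date or adult_from")
        if (self.birth_date is not None and self.adult_from is not None
                and self.adult_from < self.birth_date):
            raise SchemaError(
                f"individual {self.id}: adult_from precedes birth_date")
        spans = sorted((s.entry, s.exit) for s in self.residency)
        for (e1, x1), (e2, _x2) in zip(spans, spans[1:]):
            if x1 is None or e2 <= x1:
                raise SchemaError(
                    f"individual {self.id}: overlapping residency spells")

    def adulthood_date(self) -> dt.date:
        if self.birth_date is not None:
            return add_years(self.birth_date, ADULT_AGE_YEARS)
        return self.adult_from  # type: ignore[return-value]

    def is_adult_on(self, date: dt.date) -> bool:
        return date >= self.adulthood_date()

    def is_resident(self, group_id: str, date: dt.date) -> bool:
        return any(s.covers(group_id, date) for s in self.residency)

    def residency_overlap_days(self, group_id: str,
                               start: dt.date, end: dt.date) -> int:
        return sum(s.overlap_days(start, end) for s in self.residency
                   if s.group_id == group_id)


class ScanTable:
    """An ordered collection of scans plus the individual roster.

    ``records`` is a DataFrame with columns ``date`` (datetime64),
    ``scan_time``, ``group_id``, ``focal_id``, ``focal_activity`` and
    ``neighbours`` (tuple of IDs).  ``roster`` maps ID -> Individual.
    """

    def __init__(self, records: pd.DataFrame, roster: dict[str, Individual],
                 validate: bool = True):
        self.records = records.reset_index(drop=True)
        self.roster = roster
        if validate:
            errors = self.validate()
            if errors:
                raise ValidationError(errors)

    # -- construction --------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[ScanRecord],
                     roster: dict[str, Individual],
                     validate: bool = True) -> "ScanTable":
        rows = list(records)
        df = pd.DataFrame({
            "date": pd.to_datetime([r.date for r in rows]),
            "scan_time": [r.scan_time for r in rows],
            "group_id": [r.group_id for r in rows],
            "focal_id": [r.focal_id for r in rows],
            "focal_activity": [r.focal_activity for r in rows],
            "neighbours": [tuple(sorted(r.neighbours_5m)) for r in rows],
        })
        return cls(df, roster, validate=validate)

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_scans(self) -> int:
        return len(self.records)

    @property
    def groups(self) -> list[str]:
        return sorted(self.records["group_id"].unique())

    def iter_records(self) -> Iterator[ScanRecord]:
        for row in self.records.itertuples(index=False):
            yield ScanRecord(
                date=row.date.date(),
                group_id=row.group_id,
                focal_id=row.focal_id,
                neighbours_5m=frozenset(row.neighbours),
                focal_activity=row.focal_activity,
                scan_time=row.scan_time,
            )

    def subset(self, mask: np.ndarray) -> "ScanTable":
        return ScanTable(self.records.loc[mask], self.roster, validate=False)

    # -- validation ----------------------------------------------------
    def validate(self) -> list[str]:
        """Check every row; return a report of violations (empty if clean)."""
        errors: list[str] = []
        dates = self.records["date"].dt.date.to_numpy()
        for i, row in enumerate(self.records.itertuples(index=False)):
            if row.focal_activity not in ACTIVITIES:
                errors.append(f"row {i}: unknown activity {row.focal_activity!r}")
            if row.focal_id not in self.roster:
                errors.append(f"row {i}: unknown focal ID {row.focal_id!r}")
                continue
            nbs = row.neighbours
            if len(set(nbs)) != len(nbs):
                errors.append(f"row {i}: duplicate IDs in neighbour list")
            if row.focal_id in nbs:
                errors.append(
                    f"row {i}: focal {row.focal_id} in its own neighbour list")
            for nb in nbs:
                if nb not in self.roster:
                    errors.append(f"row {i}: unknown neighbour ID {nb!r}")
            ind = self.roster[row.focal_id]
            if not ind.is_resident(row.group_id, dates[i]):
                errors.append(
                    f"row {i}: focal {row.focal_id} not resident in "
                    f"{row.group_id} on {dates[i]}")
        return errors


@dataclass(frozen=True)
class AlphaSpell:
    group_id: str
    start: dt.date
    end: dt.date | None
    alpha_id: str


class AlphaSchedule:
    """Piecewise-constant map (group, date) -> current alpha male."""

    def __init__(self, spells: Iterable[AlphaSpell]):
        self.spells = sorted(spells, key=lambda s: (s.group_id, s.start))

    def alpha_on(self, group_id: str, date: dt.date) -> str:
        for s in self.spells:
            if (s.group_id == group_id and s.start <= date
                    and (s.end is None or date <= s.end)):
                return s.alpha_id
        raise ConfigurationError(
            f"no alpha defined for group {group_id} on {date}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group_id": [s.group_id for s in self.spells],
            "start_date": [s.start.isoformat() for s in self.spells],
            "end_date": ["" if s.end is None else s.end.isoformat()
                         for s in self.spells],
            "alpha_id": [s.alpha_id for s in self.spells],
        })


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_roster(path) -> dict[str, Individual]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ROSTER_COLUMNS, "roster")
    roster: dict[str, Individual] = {}
    for row in df.itertuples(index=False):
        spell = ResidencySpell(
            group_id=row.group_id,
            entry=_parse_date(row.entry_date, "entry"),
            exit=_parse_date(row.exit_date, "exit"),
        )
        if row.id in roster:
            ind = roster[row.id]
            ind.residency.append(spell)
            # re-run the overlap check
            Individual(ind.id, ind.sex, ind.birth_date, ind.adult_from,
                       ind.residency, ind.is_potential_alpha)
        else:
            roster[row.id] = Individual(
                id=row.id,
                sex=row.sex.strip(),
                birth_date=_parse_date(row.birth_date, "birth"),
                adult_from=_parse_date(row.adult_from, "adult_from"),
                residency=[spell],
                is_potential_alpha=str(row.is_potential_alpha).strip() in
                ("1", "true", "True"),
            )
    return roster


def read_scans(path, roster_path) -> ScanTable:
    """Read and validate a scan table; raises ValidationError with a full
    per-row report if any row violates the invariants."""
    roster = read_roster(roster_path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SCAN_COLUMNS, "scans")
    records = pd.DataFrame({
        "date": pd.to_datetime(df["date"], format="%Y-%m-%d"),
        "scan_time": [t if t else None for t in df["scan_time"]],
        "group_id": df["group_id"].to_numpy(),
        "focal_id": df["focal_id"].to_numpy(),
        "focal_activity": [a if a else "unknown"
                           for a in df["focal_activity"]],
        "neighbours": [tuple(sorted(p for p in s.split(";") if p))
                       for s in df["neighbours_5m"]],
    })
    return ScanTable(records, roster, validate=True)


def write_scans(table: ScanTable, path) -> None:
    df = table.records
    out = pd.DataFrame({
        "date": df["date"].dt.strftime("%Y-%m-%d"),
        "scan_time": ["" if t is None else t for t in df["scan_time"]],
        "group_id": df["group_id"],
        "focal_id": df["focal_id"],
        "focal_activity": df["focal_activity"],
        "neighbours_5m": [";".join(nbs) for nbs in df["neighbours"]],
    })
    out.to_csv(path, index=False)


def write_roster(roster: dict[str, Individual], path) -> None:
    rows = []
    for ind in sorted(roster.values(), key=lambda x: x.id):
        for s in sorted(ind.residency, key=lambda s: s.entry):
            rows.append({
                "id": ind.id,
                "sex": ind.sex,
                "birth_date": "" if ind.birth_date is None
                              else ind.birth_date.isoformat(),
                "adult_from": "" if ind.adult_from is None
                              else ind.adult_from.isoformat(),
                "group_id": s.group_id,
                "entry_date": s.entry.isoformat(),
                "exit_date": "" if s.exit is None else s.exit.isoformat(),
                "is_potential_alpha": int(ind.is_potential_alpha),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_alpha_schedule(path) -> AlphaSchedule:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ("group_id", "start_date", "end_date", "alpha_id"),
                     "alpha_schedule")
    spells = [AlphaSpell(r.group_id, _parse_date(r.start_date, "start"),
                         _parse_date(r.end_date, "end"), r.alpha_id)
              for r in df.itertuples(index=False)]
    return AlphaSchedule(spells)


def write_alpha_schedule(schedule: AlphaSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------
# selections and stratification
# ---------------------------------------------------------------------

def adult_females_at(table: ScanTable, group_id: str,
                     date: dt.date) -> set[str]:
    """Females resident in `group_id` on `date` and adult (>= 10 years,
    inclusive of the 10th birthday; or past their explicit adult_from)."""
    known = {s.group_id for ind in table.roster.values()
             for s in ind.residency}
    if group_id not in known:
        raise UnknownGroupError(group_id)
    return {ind.id for ind in table.roster.values()
            if ind.sex == "F" and ind.is_adult_on(date)
            and ind.is_resident(group_id, date)}


def stratify_by_alpha(table: ScanTable, schedule: AlphaSchedule,
                      mode: str = "within_5m"
                      ) -> tuple[ScanTable, ScanTable]:
    """Partition scans into (alpha-present, alpha-absent) strata.

    Presence is operationalized as the current alpha male being recorded
    within 5 m of the focal at that scan — proximity to the focal is the
    only alpha-location datum the scan protocol collects.  ``mode`` is a
    hook for datasets that carry an in-view column; only ``within_5m`` is
    implemented.
    """
    if mode != "within_5m":
        raise ConfigurationError(f"unsupported presence mode {mode!r}")
    dates = table.records["date"].dt.date.to_numpy()
    groups = table.records["group_id"].to_numpy()
    nbs = table.records["neighbours"].to_numpy()
    present = np.zeros(len(table.records), dtype=bool)
    cache: dict[tuple[str, dt.date], str] = {}
    for i in range(len(table.records)):
        key = (groups[i], dates[i])
        alpha = cache.get(key)
        if alpha is None:
            alpha = schedule.alpha_on(*key)
            cache[key] = alpha
        present[i] = alpha in nbs[i]
    return table.subset(present), table.subset(~present)
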