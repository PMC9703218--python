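"""Elo-rating dominance hierarchies for identifying the alpha male.

Decided agonistic interactions are processed in chronological order.
With ratings R_w (winner) and R_l (loser), the expected win probability
is E_w = 1 / (1 + 10^((R_l - R_w)/400)); the winner gains k*(1 - E_w)
and the loser loses the same amount, so the rating sum is conserved.
Defaults (k = 100, start 1000) are the conventional animal-behaviour
parameterization and are configurable.

The alpha schedule is the piecewise-constant trajectory of the
top-rated potential-alpha male resident in the group; ties are broken
toward longer group tenure, then the lexicographically smaller ID, and
flagged.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .io import (AlphaSchedule, AlphaSpell, Individual, SchemaError,
                 ValidationError, _parse_date, _require_columns)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgonisticEvent:
    date: dt.date
    group_id: str
    winner_id: str
    loser_id: str
    decided: bool = True

    def __post_init__(self):
        if self.winner_id == self.loser_id:
            raise ValidationError(
                [f"agonistic event on {self.date}: winner equals loser "
                 f"({self.winner_id})"])


@dataclass
class EloState:
    ratings: dict[str, float] = field(default_factory=dict)
    k: float = 100.0
    start_rating: float = 1000.0

    def rating(self, id: str) -> float:
        return self.ratings.get(id, self.start_rating)


def expected_win(r_winner: float, r_loser: float) -> float:
    return 1.0 / (1.0 + 10.0 ** ((r_loser - r_winner) / 400.0))


def elo_update(state: EloState, event: AgonisticEvent) -> EloState:
    """Apply one decided interaction; returns a new state (the input is
    not mutated).  Undecided events are skipped with a log entry."""
    if not event.decided:
        log.info("skipping undecided event on %s (%s vs %s)",
                 event.date, event.winner_id, event.loser_id)
        return state
    ratings = dict(state.ratings)
    rw = state.rating(event.winner_id)
    rl = state.rating(event.loser_id)
    delta = state.k * (1.0 - expected_win(rw, rl))
    ratings[event.winner_id] = rw + delta
    ratings[event.loser_id] = rl - delta
    return replace(state, ratings=ratings)


def read_agonistic(path) -> list[AgonisticEvent]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ("date", "group_id", "winner_id", "loser_id",
                          "decided"), "agonistic")
    return [AgonisticEvent(_parse_date(r.date, "event"), r.group_id,
                           r.winner_id, r.loser_id,
                           str(r.decided).strip() in ("1", "true", "True"))
            for r in df.itertuples(index=False)]


def _tenure_key(ind: Individual, group_id: str):
    entries = [s.entry for s in ind.residency if s.group_id == group_id]
    return (min(entries) if entries else dt.date.max, ind.id)


def _top_male(state: EloState, males: Sequence[Individual],
              group_id: str, date: dt.date) -> tuple[str | None, bool]:
    resident = [m for m in males if m.is_resident(group_id, date)]
    if not resident:
        return None, False
    best = max(state.rating(m.id) for m in resident)
    winners = [m for m in resident if state.rating(m.id) == best]
    winners.sort(key=lambda m: _tenure_key(m, group_id))
    return winners[0].id, len(winners) > 1


def alpha_schedule(events: Iterable[AgonisticEvent],
                   roster: dict[str, Individual],
                   k: float = 100.0, start_rating: float = 1000.0
                   ) -> tuple[AlphaSchedule, pd.DataFrame]:
    """Derive the per-group alpha schedule from agonistic interactions.

    Returns the schedule plus a ratings timeline (one row per decided
    event, post-update).  Groups with a single potential-alpha male get
    one spell covering his residency; a multi-male group with no events
    starts with all males tied at the start rating (tie flagged).
    """
    males_by_group: dict[str, list[Individual]] = {}
    for ind in roster.values():
        if ind.sex == "M" and ind.is_potential_alpha:
            for s in ind.residency:
                males_by_group.setdefault(s.group_id, []).append(ind)

    events = sorted(events, key=lambda e: (e.date, e.group_id,
                                           e.winner_id, e.loser_id))
    by_group: dict[str, list[AgonisticEvent]] = {}
    for e in events:
        by_group.setdefault(e.group_id, []).append(e)

    spells: list[AlphaSpell] = []
    timeline_rows = []
    for gid in sorted(males_by_group):
        males = sorted({m.id: m for m in males_by_group[gid]}.values(),
                       key=lambda m: m.id)
        for e in by_group.get(gid, []):
            for mid in (e.winner_id, e.loser_id):
                if mid not in {m.id for m in males}:
                    raise ValidationError(
                        [f"{mid} is not a potential-alpha male of {gid}"])
        state = EloState(k=k, start_rating=start_rating)
        boundaries = sorted({s.entry for m in males for s in m.residency
                             if s.group_id == gid}
                            | {s.exit + dt.timedelta(days=1)
                               for m in males for s in m.residency
                               if s.group_id == gid and s.exit is not None}
                            | {e.date for e in by_group.get(gid, [])})
        group_events = by_group.get(gid, [])
        ei = 0
        current: str | None = None
        current_start: dt.date | None = None
        for day in boundaries:
            while ei < len(group_events) and group_events[ei].date <= day:
                e = group_events[ei]
                if e.decided:
                    state = elo_update(state, e)
                    timeline_rows.append({
                        "date": e.date.isoformat(), "group_id": gid,
                        "winner_id": e.winner_id, "loser_id": e.loser_id,
                        "rating_winner": state.rating(e.winner_id),
                        "rating_loser": state.rating(e.loser_id)})
                ei += 1
            top, tie = _top_male(state, males, gid, day)
            if tie:
                warnings.warn(f"{gid}: alpha tie on {day}, broken by "
                              "tenure then ID")
            if top != current:
                if current is not None:
                    spells.append(AlphaSpell(gid, current_start,
                                             day - dt.timedelta(days=1),
                                             current))
                elif current_start is not None:
                    warnings.warn(f"{gid}: no resident male from "
                                  f"{current_start} to {day}")
                current, current_start = top, day
        if current is not None:
            exits = [s.exit for m in males for s in m.residency
                     if s.group_id == gid]
            end = None if any(x is None for x in exits) else max(exits)
            spells.append(AlphaSpell(gid, current_start, end, current))
    timeline = pd.DataFrame(timeline_rows, columns=[
        "date", "group_id", "winner_id", "loser_id",
        "rating_winner", "rating_loser"])
    return AlphaSchedule(spells), timeline
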