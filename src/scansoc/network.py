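"""Annual association networks from scan data.

Scans are aggregated per group into consecutive 365-day windows anchored
at the group's first observation date.  Within a window, the association
(strength) score of a female dyad is

    strength = N_ab / (N_a + N_b)

where N_a and N_b are the numbers of scans in which a and b were the
focal animal, and N_ab is the number of scans in which the two were
recorded within 5 m of each other (one was focal with the other in its
neighbour list).  The score is the weighted-degree edge value of the
annual association network.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (AlphaSchedule, ParameterError, ScanTable, adult_females_at)

STRATA = ("all", "alpha_present", "alpha_absent")


def canonical_dyad(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class WindowKey:
    """A half-open [start, end) analysis window within one group."""

    group_id: str
    window_index: int
    start: dt.date
    end: dt.date
    partial: bool = False

    @property
    def days(self) -> int:
        return (self.end - self.start).days


@dataclass
class DyadCounts:
    id_a: str
    id_b: str
    n_a: int
    n_b: int
    n_ab: int

    @property
    def denominator(self) -> int:
        return self.n_a + self.n_b

    @property
    def strength(self) -> float:
        if self.denominator == 0:
            raise ZeroDivisionError(
                f"dyad ({self.id_a},{self.id_b}) has no focal scans")
        return self.n_ab / self.denominator


@dataclass
class AssociationNetwork:
    """Weighted undirected association network for one group-window-stratum."""

    window: WindowKey
    stratum: str
    members: tuple[str, ...]
    dyads: dict[tuple[str, str], DyadCounts]
    dropped: tuple[tuple[str, str], ...] = ()
    empty: bool = False

    def strength(self, a: str, b: str) -> float:
        return self.dyads[canonical_dyad(a, b)].strength

    def dyad_order(self) -> list[tuple[str, str]]:
        return sorted(self.dyads)

    def n_events(self) -> int:
        return sum(d.n_ab for d in self.dyads.values())

    def partners_of(self, id: str) -> list[str]:
        return [b if a == id else a for (a, b) in self.dyads if id in (a, b)]


def build_windows(table: ScanTable, window_days: int = 365,
                  anchors: dict[str, dt.date] | None = None
                  ) -> list[WindowKey]:
    """Consecutive windows per group, anchored at the group's first scan
    date (or an explicit per-group anchor).  A trailing window that the
    data do not fully cover is flagged ``partial``."""
    if window_days <= 0:
        raise ParameterError("window_days must be positive")
    if len(table) == 0:
        raise ParameterError("empty scan table")
    out: list[WindowKey] = []
    dates = table.records["date"].dt.date
    for gid, sub in table.records.groupby("group_id", sort=True):
        gdates = dates.loc[sub.index]
        first, last = gdates.min(), gdates.max()
        start = (anchors or {}).get(gid, first)
        idx = 0
        while start <= last:
            end = start + dt.timedelta(days=window_days)
            partial = last < end - dt.timedelta(days=1)
            out.append(WindowKey(gid, idx, start, end, partial=partial))
            start, idx = end, idx + 1
    return out


def _window_members(table: ScanTable, window: WindowKey,
                    min_overlap_days: int | None) -> tuple[str, ...]:
    """Adult females counted as network members for the window: adult by
    the window start and co-resident for at least ``min_overlap_days``
    (default: the full window)."""
    need = window.days if min_overlap_days is None else min_overlap_days
    members = []
    for ind in table.roster.values():
        if ind.sex != "F" or not ind.is_adult_on(window.start):
            continue
        if ind.residency_overlap_days(window.group_id, window.start,
                                      window.end) >= need:
            members.append(ind.id)
    return tuple(sorted(members))


def _stratum_mask(table: ScanTable, sub: pd.DataFrame, stratum: str,
                  alpha_schedule: AlphaSchedule | None) -> np.ndarray:
    if stratum == "all":
        return np.ones(len(sub), dtype=bool)
    if stratum not in STRATA:
        raise ParameterError(f"unknown stratum {stratum!r}")
    if alpha_schedule is None:
        raise ParameterError(f"stratum {stratum!r} requires an alpha schedule")
    dates = sub["date"].dt.date.to_numpy()
    nbs = sub["neighbours"].to_numpy()
    gids = sub["group_id"].to_numpy()
    present = np.fromiter(
        (alpha_schedule.alpha_on(g, d) in nb
         for g, d, nb in zip(gids, dates, nbs)),
        dtype=bool, count=len(sub))
    return present if stratum == "alpha_present" else ~present


def count_dyads(table: ScanTable, window: WindowKey, stratum: str = "all",
                alpha_schedule: AlphaSchedule | None = None,
                min_overlap_days: int | None = None) -> AssociationNetwork:
    """Tally focal counts and co-proximity events for every member dyad.

    A scan where ``a`` is focal and ``b`` appears in its neighbour list
    contributes one co-proximity event to the dyad (a, b) and one focal
    scan to N_a.  Dyads whose combined focal count is zero carry an
    undefined score and are dropped with a warning.
    """
    members = _window_members(table, window, min_overlap_days)
    rec = table.records
    dates = rec["date"].to_numpy()
    in_win = ((dates >= np.datetime64(window.start)) &
              (dates < np.datetime64(window.end)) &
              (rec["group_id"].to_numpy() == window.group_id))
    sub = rec.loc[in_win]
    sub = sub.loc[_stratum_mask(table, sub, stratum, alpha_schedule)]

    mset = set(members)
    n_focal = {m: 0 for m in members}
    n_ab: dict[tuple[str, str], int] = {}
    for focal, nbs in zip(sub["focal_id"].to_numpy(),
                          sub["neighbours"].to_numpy()):
        if focal not in mset:
            continue
        n_focal[focal] += 1
        for nb in nbs:
            if nb in mset and nb != focal:
                key = canonical_dyad(focal, nb)
                n_ab[key] = n_ab.get(key, 0) + 1

    dyads: dict[tuple[str, str], DyadCounts] = {}
    dropped: list[tuple[str, str]] = []
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            key = (a, b)
            dc = DyadCounts(a, b, n_focal[a], n_focal[b], n_ab.get(key, 0))
            if dc.denominator == 0:
                dropped.append(key)
            else:
                dyads[key] = dc
    if dropped:
        warnings.warn(
            f"{window.group_id} window {window.window_index} "
            f"({stratum}): dropped {len(dropped)} dyad(s) with no focal scans")
    empty = all(v == 0 for v in n_focal.values())
    return AssociationNetwork(window, stratum, members, dyads,
                              dropped=tuple(dropped), empty=empty)


def no_female_scan_fraction(table: ScanTable,
                            groups: Iterable[str] | None = None) -> float:
    """Fraction of adult-female focal scans with no other adult female of
    the same group within 5 m."""
    scope = set(table.groups if groups is None else groups)
    if not scope:
        raise ParameterError("empty group scope")
    rec = table.records
    roster = table.roster
    dates = rec["date"].dt.date.to_numpy()
    denom = num = 0
    for gid, focal, nbs, d in zip(rec["group_id"].to_numpy(),
                                  rec["focal_id"].to_numpy(),
                                  rec["neighbours"].to_numpy(), dates):
        if gid not in scope:
            continue
        f = roster.get(focal)
        if f is None or f.sex != "F" or not f.is_adult_on(d):
            continue
        denom += 1
        has_female = any(
            (o := roster.get(nb)) is not None and o.sex == "F"
            and o.is_adult_on(d) and o.is_resident(gid, d)
            for nb in nbs)
        if not has_female:
            num += 1
    if denom == 0:
        raise ParameterError("no adult-female focal scans in scope")
    return num / denom


class NoPartnerError(LookupError):
    pass


def top_partner(network: AssociationNetwork, id: str) -> tuple[str, bool]:
    """Partner with the maximal strength involving `id`.  Ties are broken
    toward the lexicographically smaller partner ID and flagged."""
    if id not in network.members:
        raise NoPartnerError(f"{id} not a member of the network")
    scores = [(b if a == id else a, dc.strength)
              for (a, b), dc in network.dyads.items() if id in (a, b)]
    if not scores:
        raise NoPartnerError(f"{id} has no co-resident partners")
    best = max(s for _, s in scores)
    winners = sorted(p for p, s in scores if s == best)
    return winners[0], len(winners) > 1


# ---------------------------------------------------------------------
# export
# ---------------------------------------------------------------------

def networks_to_frame(networks: Sequence[AssociationNetwork]) -> pd.DataFrame:
    rows = []
    for net in networks:
        for (a, b), dc in sorted(net.dyads.items()):
            rows.append({
                "group_id": net.window.group_id,
                "window_index": net.window.window_index,
                "window_start": net.window.start.isoformat(),
                "stratum": net.stratum,
                "id_a": a, "id_b": b,
                "N_a": dc.n_a, "N_b": dc.n_b, "N_ab": dc.n_ab,
                "strength": dc.strength,
            })
    return pd.DataFrame(rows, columns=[
        "group_id", "window_index", "window_start", "stratum",
        "id_a", "id_b", "N_a", "N_b", "N_ab", "strength"])


def to_graphml(network: AssociationNetwork, path) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(network.members)
    for (a, b), dc in network.dyads.items():
        g.add_edge(a, b, weight=dc.strength, n_ab=dc.n_ab)
    nx.write_graphml(g, path)
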