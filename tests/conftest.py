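from __future__ import annotations

import datetime as dt

import pytest

from scansoc.io import (AlphaSchedule, AlphaSpell, Individual,
                        ResidencySpell, ScanRecord, ScanTable)

GROUP = "G1"
START = dt.date(2015, 1, 1)


def make_individual(id: str, sex: str = "F",
                    birth: dt.date | None = dt.date(2000, 1, 1),
                    adult_from: dt.date | None = None,
                    group: str = GROUP,
                    entry: dt.date = dt.date(2014, 1, 1),
                    exit: dt.date | None = None,
                    alpha: bool = False) -> Individual:
    return Individual(id=id, sex=sex, birth_date=birth,
                      adult_from=adult_from,
                      residency=[ResidencySpell(group, entry, exit)],
                      is_potential_alpha=alpha)


def scan(focal: str, neighbours=(), date: dt.date = START,
         group: str = GROUP, time: str | None = "08:00") -> ScanRecord:
    return ScanRecord(date=date, group_id=group, focal_id=focal,
                      neighbours_5m=frozenset(neighbours),
                      scan_time=time)


@pytest.fixture
def roster4():
    """Four adult females plus a potential-alpha male."""
    r = {i: make_individual(i) for i in ("a", "b", "c", "d")}
    r["m1"] = make_individual("m1", sex="M", alpha=True)
    return r


@pytest.fixture
def five_scan_table(roster4):
    """a focal x3 with b near twice; b focal x2 with a near once."""
    records = [
        scan("a", {"b"}),
        scan("a", {"b", "c"}),
        scan("a", ()),
        scan("b", {"a"}),
        scan("b", {"c"}),
    ]
    return ScanTable.from_records(records, roster4)


@pytest.fixture
def alpha_schedule4():
    return AlphaSchedule([AlphaSpell(GROUP, dt.date(2014, 1, 1), None, "m1")])
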