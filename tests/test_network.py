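import datetime as dt

import numpy as np
import pytest

import _oracles as oracles
from conftest import GROUP, START, make_individual, scan
from scansoc.io import ParameterError, ScanTable
from scansoc.network import (NoPartnerError, build_windows, count_dyads,
                             no_female_scan_fraction, top_partner)
from scansoc.nullmodel import PermutationConfig  # noqa: F401 (API check)
from scansoc.synth import SyntheticConfig, alpha_schedule_for, generate


def _table_spanning(roster, n_days):
    recs = [scan("a", (), date=START + dt.timedelta(days=d))
            for d in (0, n_days - 1)]
    return ScanTable.from_records(recs, roster)


class TestWindows:
    def test_two_complete_years(self, roster4):
        wins = build_windows(_table_spanning(roster4, 730))
        assert [w.partial for w in wins] == [False, False]
        assert wins[1].start == START + dt.timedelta(days=365)

    def test_trailing_partial_window_flagged(self, roster4):
        wins = build_windows(_table_spanning(roster4, 400))
        assert [w.partial for w in wins] == [False, True]

    def test_bad_window_length(self, roster4):
        with pytest.raises(ParameterError):
            build_windows(_table_spanning(roster4, 10), window_days=0)

    def test_generator_years_align_with_windows(self):
        cfg = SyntheticConfig(n_years=5, scans_per_female_year=60, seed=4)
        table, truth = generate(cfg)
        wins = [w for w in build_windows(table) if not w.partial]
        assert [w.start for w in wins] == truth.year_starts["G1"]


class TestCountDyads:
    def test_hand_enumerated_fixture(self, five_scan_table):
        win = build_windows(five_scan_table)[0]
        net = count_dyads(five_scan_table, win, min_overlap_days=1)
        dc = net.dyads[("a", "b")]
        assert (dc.n_a, dc.n_b, dc.n_ab) == (3, 2, 3)
        assert dc.strength == pytest.approx(0.6)

    def test_never_associated_dyad_scores_zero(self, five_scan_table):
        win = build_windows(five_scan_table)[0]
        net = count_dyads(five_scan_table, win, min_overlap_days=1)
        # d was focal never and near nobody: dropped (no focal scans)
        assert ("a", "d") in net.dropped or net.dyads[("a", "d")].n_ab == 0
        # c never focal, but a and b were: zero strength via partners
        assert net.dyads[("b", "c")].n_ab == 1

    def test_matches_bruteforce_recount_on_random_fixtures(self, roster4):
        rng = np.random.default_rng(42)
        ids = ["a", "b", "c", "d"]
        for trial in range(20):
            recs = []
            for i in range(int(rng.integers(5, 50))):
                focal = ids[rng.integers(4)]
                others = [x for x in ids if x != focal]
                nbs = [x for x in others if rng.random() < 0.4]
                recs.append(scan(focal, nbs,
                                 date=START + dt.timedelta(
                                     days=int(rng.integers(0, 300)))))
            table = ScanTable.from_records(recs, roster4)
            win = build_windows(table)[0]
            net = count_dyads(table, win, min_overlap_days=1)
            plain = list(table.iter_records())
            for (a, b), dc in net.dyads.items():
                na, nb, nab = oracles.brute_dyad_counts(plain, a, b)
                assert (dc.n_a, dc.n_b, dc.n_ab) == (na, nb, nab)
                assert 0.0 <= dc.strength <= 1.0

    def test_strength_monotone_in_events(self, five_scan_table):
        win = build_windows(five_scan_table)[0]
        before = count_dyads(five_scan_table, win,
                             min_overlap_days=1).dyads[("a", "b")]
        recs = list(five_scan_table.iter_records())
        plus_event = ScanTable.from_records(
            recs + [scan("a", {"b"})], five_scan_table.roster)
        after = count_dyads(plus_event, win,
                            min_overlap_days=1).dyads[("a", "b")]
        assert after.strength >= before.strength
        plus_empty = ScanTable.from_records(
            recs + [scan("a", ())], five_scan_table.roster)
        diluted = count_dyads(plus_empty, win,
                              min_overlap_days=1).dyads[("a", "b")]
        assert diluted.strength <= before.strength

    def test_stratum_counts_are_additive(self):
        cfg = SyntheticConfig(n_years=1, scans_per_female_year=120, seed=9)
        table, truth = generate(cfg)
        sched = alpha_schedule_for(truth)
        win = build_windows(table)[0]
        full = count_dyads(table, win)
        pres = count_dyads(table, win, "alpha_present", sched)
        absn = count_dyads(table, win, "alpha_absent", sched)
        for key, dc in full.dyads.items():
            pa = pres.dyads.get(key)
            ab = absn.dyads.get(key)
            assert dc.n_ab == ((pa.n_ab if pa else 0)
                               + (ab.n_ab if ab else 0))
            assert dc.n_a == ((pa.n_a if pa else 0) + (ab.n_a if ab else 0))
            assert dc.n_b == ((pa.n_b if pa else 0) + (ab.n_b if ab else 0))

    def test_midwindow_immigrant_excluded_by_default(self, roster4):
        roster = dict(roster4)
        roster["late"] = make_individual("late",
                                         entry=dt.date(2015, 6, 1))
        recs = [scan("a", {"b"}, date=START + dt.timedelta(days=d))
                for d in (0, 364)]
        table = ScanTable.from_records(recs, roster)
        win = build_windows(table)[0]
        net = count_dyads(table, win)
        assert "late" not in net.members
        relaxed = count_dyads(table, win, min_overlap_days=30)
        assert "late" in relaxed.members


class TestNoFemaleFraction:
    def test_fixture_fraction(self, roster4):
        recs = ([scan("a", {"b"}, date=START + dt.timedelta(days=i))
                 for i in range(7)]
                + [scan("a", {"m1"}, date=START + dt.timedelta(days=7 + i))
                   for i in range(3)])
        table = ScanTable.from_records(recs, roster4)
        assert no_female_scan_fraction(table) == pytest.approx(0.3)

    def test_all_scans_with_female_neighbour(self, roster4):
        table = ScanTable.from_records([scan("a", {"b"})], roster4)
        assert no_female_scan_fraction(table) == 0.0

    def test_empty_scope_rejected(self, five_scan_table):
        with pytest.raises(ParameterError):
            no_female_scan_fraction(five_scan_table, groups=[])


class TestTopPartner:
    def _net(self, strengths, roster4):
        # build records so that a's dyads have the desired N_ab with
        # shared denominators: a focal 100 times
        recs = []
        day = 0
        for partner, n in strengths.items():
            for _ in range(n):
                recs.append(scan("a", {partner},
                                 date=START + dt.timedelta(days=day % 300)))
                day += 1
        table = ScanTable.from_records(recs, roster4)
        win = build_windows(table)[0]
        return count_dyads(table, win, min_overlap_days=1)

    def test_argmax_partner(self, roster4):
        net = self._net({"b": 10, "c": 4, "d": 7}, roster4)
        assert top_partner(net, "a") == ("b", False)

    def test_tie_broken_lexicographically_and_flagged(self, roster4):
        net = self._net({"c": 5, "b": 5}, roster4)
        assert top_partner(net, "a") == ("b", True)

    def test_single_partner(self, roster4):
        net = self._net({"b": 3}, roster4)
        partner, tie = top_partner(net, "a")
        assert partner == "b" and tie is False

    def test_no_partner_error(self, roster4):
        net = self._net({"b": 3}, roster4)
        with pytest.raises(NoPartnerError):
            top_partner(net, "zz")
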