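import datetime as dt

import numpy as np
import pytest
from scipy import stats as sps

import _oracles as oracles
from scansoc.consistency import (AlignmentError, DyadVector,
                                 InsufficientDataError, align_networks,
                                 alpha_similarity_report,
                                 build_consistency_table, consistency_stats,
                                 cosine_similarity)
from scansoc.network import (AssociationNetwork, DyadCounts, WindowKey,
                             build_windows, count_dyads)
from scansoc.synth import SyntheticConfig, alpha_schedule_for, generate


def vec(*weights):
    dyads = tuple((f"x{i}", f"y{i}") for i in range(len(weights)))
    return DyadVector(dyads, np.array(weights, dtype=float))


def vec_pair(wa, wb):
    dyads = tuple((f"x{i}", f"y{i}") for i in range(len(wa)))
    return (DyadVector(dyads, np.array(wa, float)),
            DyadVector(dyads, np.array(wb, float)))


class TestCosine:
    def test_identical_networks_score_one(self):
        a, b = vec_pair([0.2, 0.1, 0.4], [0.2, 0.1, 0.4])
        assert cosine_similarity(a, b).value == pytest.approx(1.0)

    def test_orthogonal_networks_score_zero(self):
        a, b = vec_pair([1, 0, 0], [0, 1, 0])
        assert cosine_similarity(a, b).value == pytest.approx(0.0)

    def test_shared_half_association(self):
        a, b = vec_pair([1, 1, 0], [1, 0, 0])
        assert cosine_similarity(a, b).value == pytest.approx(
            1 / np.sqrt(2), abs=5e-6)

    def test_scale_invariance_and_symmetry(self):
        rng = np.random.default_rng(12)
        wa, wb = rng.random(30), rng.random(30)
        a, b = vec_pair(wa, wb)
        ca, _ = vec_pair(wa * 7.3, wb)
        assert cosine_similarity(ca, b).value == pytest.approx(
            cosine_similarity(a, b).value, abs=1e-12)
        assert cosine_similarity(b, a).value == pytest.approx(
            cosine_similarity(a, b).value, abs=1e-15)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(13)
        for n in (2, 10, 100):
            wa, wb = rng.random(n), rng.random(n)
            a, b = vec_pair(wa, wb)
            assert cosine_similarity(a, b).value == pytest.approx(
                oracles.cosine_direct(wa, wb), abs=1e-12)

    def test_zero_norm_is_degenerate_not_zero(self):
        a, b = vec_pair([0, 0], [1, 2])
        res = cosine_similarity(a, b)
        assert res.degenerate and res.value is None

    def test_misaligned_vectors_rejected(self):
        a = DyadVector((("a", "b"),), np.array([1.0]))
        b = DyadVector((("a", "c"),), np.array([1.0]))
        with pytest.raises(AlignmentError):
            cosine_similarity(a, b)

    def test_bounds_on_random_nonnegative_vectors(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            a, b = vec_pair(rng.random(8), rng.random(8))
            v = cosine_similarity(a, b).value
            assert 0.0 <= v <= 1.0


WIN0 = WindowKey("G1", 0, dt.date(2015, 1, 1), dt.date(2016, 1, 1))
WIN1 = WindowKey("G1", 1, dt.date(2016, 1, 1), dt.date(2016, 12, 31))


def net_from_strengths(window, strengths, denom=100):
    dyads = {tuple(sorted(k)): DyadCounts(*sorted(k), denom // 2,
                                          denom // 2,
                                          int(v * denom))
             for k, v in strengths.items()}
    members = tuple(sorted({m for k in strengths for m in k}))
    return AssociationNetwork(window, "all", members, dyads)


class TestConsistencyTable:
    def test_identical_networks_give_perfect_lag_agreement(self):
        s = {("a", "b"): 0.30, ("a", "c"): 0.10, ("b", "c"): 0.20}
        rows = build_consistency_table(
            [net_from_strengths(WIN0, s), net_from_strengths(WIN1, s)])
        t1 = rows[rows.window_index == 1]
        assert (t1["strength_t"] == t1["strength_lag1"]).all()
        trues = t1.dropna(subset=["is_top_lag1"])
        assert (trues["is_top_t"] == trues["is_top_lag1"]).all()

    def test_emigrated_member_has_no_lag_row(self):
        s0 = {("a", "b"): 0.3, ("a", "c"): 0.1, ("b", "c"): 0.2}
        s1 = {("a", "b"): 0.3}  # c left
        rows = build_consistency_table(
            [net_from_strengths(WIN0, s0), net_from_strengths(WIN1, s1)])
        t1 = rows[rows.window_index == 1]
        assert set(map(tuple, t1[["id_a", "id_b"]].values)) == {("a", "b")}
        assert t1["strength_lag1"].notna().all()

    def test_lag_joins_are_lossless(self):
        cfg = SyntheticConfig(n_years=3, scans_per_female_year=150,
                              turnover_prob=0.2, seed=31)
        table, _ = generate(cfg)
        nets = [count_dyads(table, w) for w in build_windows(table)
                if not w.partial]
        by_key = {(n.window.group_id, n.window.window_index): n
                  for n in nets}
        rows = build_consistency_table(nets)
        for r in rows.dropna(subset=["strength_lag1"]).itertuples():
            prev = by_key[(r.group_id, r.window_index - 1)]
            assert (r.id_a, r.id_b) in prev.dyads
            assert prev.dyads[(r.id_a, r.id_b)].strength == pytest.approx(
                r.strength_lag1)

    def test_single_window_yields_empty_table(self):
        s = {("a", "b"): 0.3}
        with pytest.warns(UserWarning):
            rows = build_consistency_table([net_from_strengths(WIN0, s)])
        assert rows.empty


class TestConsistencyStats:
    def _two_year_rows(self, strengths0, strengths1):
        return build_consistency_table(
            [net_from_strengths(WIN0, strengths0),
             net_from_strengths(WIN1, strengths1)])

    def test_identical_years_give_perfect_consistency(self):
        rng = np.random.default_rng(15)
        members = [f"f{i}" for i in range(6)]
        s = {(a, b): round(float(rng.uniform(0.01, 0.3)), 2)
             for i, a in enumerate(members) for b in members[i + 1:]}
        rows = self._two_year_rows(s, s)
        out = consistency_stats(rows, n_boot=200, seed=1, lags=(1,))
        assert out["lag_correlations"][1]["rho"] == pytest.approx(1.0)
        assert out["top_partner"]["repeat_rate"] == 1.0
        assert out["top_partner"]["chance_rate"] == pytest.approx(0.2)

    def test_insufficient_rows_rejected(self):
        rows = self._two_year_rows({("a", "b"): 0.1}, {("a", "b"): 0.2})
        with pytest.raises(InsufficientDataError):
            consistency_stats(rows, n_boot=50, seed=1)

    def test_recovers_planted_autocorrelation(self):
        cfg = SyntheticConfig(n_females=8, n_years=6,
                              scans_per_female_year=800,
                              gregariousness_sd=0.25, dyad_effect_sd=0.5,
                              preferred_fraction=0.0, alpha_effect=0.0,
                              persistence=0.6, turnover_prob=0.0, seed=32)
        table, _ = generate(cfg)
        nets = [count_dyads(table, w) for w in build_windows(table)
                if not w.partial]
        rows = build_consistency_table(nets, lags=(1,))
        out = consistency_stats(rows, n_boot=200, seed=2, lags=(1,))
        rho = out["lag_correlations"][1]["rho"]
        assert rho == pytest.approx(0.6, abs=0.2)
        assert out["lag_correlations"][1]["p"] < 0.05

    def test_uncorrelated_years_centre_on_zero(self):
        rng = np.random.default_rng(16)
        members = [f"f{i}" for i in range(7)]
        rhos = []
        for rep in range(20):
            s0 = {(a, b): float(rng.uniform(0.01, 0.3))
                  for i, a in enumerate(members) for b in members[i + 1:]}
            s1 = {k: float(rng.uniform(0.01, 0.3)) for k in s0}
            out = consistency_stats(self._two_year_rows(s0, s1),
                                    n_boot=100, seed=rep, lags=(1,))
            rhos.append(out["lag_correlations"][1]["rho"])
        assert abs(np.mean(rhos)) < 0.15


def test_alpha_similarity_converges_to_one_without_alpha_effect():
    """With no alpha effect the two strata sample the same network, so
    cosine similarity approaches 1 as scans grow."""
    cfg = SyntheticConfig(n_years=1, scans_per_female_year=2500,
                          alpha_effect=0.0, turnover_prob=0.0, seed=33)
    table, truth = generate(cfg)
    rep = alpha_similarity_report(table, alpha_schedule_for(truth))
    assert len(rep) == 1
    assert rep["cosine"].iloc[0] > 0.95
    assert not rep["degenerate"].iloc[0]


def test_alpha_similarity_flags_degenerate_stratum(roster4, alpha_schedule4):
    from conftest import scan
    from scansoc.io import ScanTable

    # alpha always present; the absent stratum has no events at all
    recs = [scan("a", {"b", "m1"}, date=dt.date(2015, 1, 1)
                 + dt.timedelta(days=i)) for i in range(365)]
    table = ScanTable.from_records(recs, roster4)
    rep = alpha_similarity_report(table, alpha_schedule4)
    assert bool(rep["degenerate"].iloc[0])
    assert np.isnan(rep["cosine"].iloc[0])
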