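"""Synthetic scan-sampling datasets with known ground truth.

The generator emulates the structure of multi-year primate proximity
data: groups of adult females scanned at 10-min intervals, focal sampling
roughly balanced across females within each month but unbalanced overall,
per-scan neighbour lists, an alpha male who is near the focal in a
tunable fraction of scans, and year-to-year persistence of social
structure.

Generative model (per scan with focal f, candidate neighbour j, alpha
presence A ~ Bernoulli(p_A)):

    P(j within 5 m of f) = logistic(beta0 + g_f + g_j + delta_fj
                                    + e_fj + beta_A * A)

where g_i is female i's gregariousness, delta_fj a fixed log-odds bonus
for *planted* preferred dyads, and e_fj a dyad-level latent effect.
g and e follow stationary Gaussian AR(1) processes across years with
coefficient rho, so social structure persists but drifts.  Neighbour
draws are independent across candidates and scans.

The latent parameters are returned as a :class:`SyntheticTruth` so
recovery and calibration experiments can score the analysis pipeline
against the planted structure.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from .io import (AlphaSchedule, AlphaSpell, Individual, ParameterError,
                 ResidencySpell, ScanTable, write_alpha_schedule,
                 write_roster, write_scans)
from .network import canonical_dyad

YEAR_DAYS = 365
_ACTIVITIES = ("feeding", "resting", "travelling", "other")
_ACTIVITY_P = (0.5, 0.3, 0.15, 0.05)


def logit(p: float) -> float:
    return math.log(p / (1 - p))


def inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-like defaults: groups of ~6 adult females observed for a few
    years at ~500 focal scans per female per year, baseline pairwise
    co-proximity ~0.04 per scan, moderately persistent structure."""

    n_groups: int = 1
    n_females: int = 6
    n_years: int = 3
    scans_per_female_year: float = 500.0
    scan_dispersion: float = 0.3        # lognormal sd of per-female-year rate
    baseline_logit: float = logit(0.035)
    gregariousness_sd: float = 0.3      # sd of g_i (log-odds)
    preferred_fraction: float = 0.10    # fraction of dyads planted
    preference_effect: float = 1.2      # delta, log-odds
    dyad_effect_sd: float = 0.25        # sd of e_ij (log-odds)
    alpha_effect: float = 0.5           # beta_A, log-odds
    alpha_presence_prob: float = 0.5
    persistence: float = 0.6            # AR(1) rho on g and e across years
    turnover_prob: float = 0.05         # per-female per year-boundary
    start_date: dt.date = dt.date(2015, 1, 1)
    seed: int | None = None

    def __post_init__(self):
        if self.n_females < 2:
            raise ParameterError("n_females must be >= 2")
        if not (0 <= self.preferred_fraction <= 1):
            raise ParameterError("preferred_fraction must be in [0, 1]")
        if not (0 <= self.alpha_presence_prob <= 1):
            raise ParameterError("alpha_presence_prob must be in [0, 1]")
        if not (0 <= self.turnover_prob <= 1):
            raise ParameterError("turnover_prob must be in [0, 1]")
        if not (-1 <= self.persistence <= 1):
            raise ParameterError("persistence must be in [-1, 1]")
        if self.n_years < 1 or self.n_groups < 1:
            raise ParameterError("n_years and n_groups must be >= 1")


@dataclass
class SyntheticTruth:
    """Latent parameters behind a generated dataset.

    Keys: ``gregariousness[gid][year][fid]``, ``dyad_effects[gid][year][(a,b)]``,
    ``planted[gid]`` (list of canonical dyads), ``females[gid][year]``,
    ``alpha[gid]``, ``year_starts[gid]`` (list of dates).
    """

    config: SyntheticConfig
    females: dict = field(default_factory=dict)
    gregariousness: dict = field(default_factory=dict)
    dyad_effects: dict = field(default_factory=dict)
    planted: dict = field(default_factory=dict)
    alpha: dict = field(default_factory=dict)
    year_starts: dict = field(default_factory=dict)

    def planted_dyads(self, gid: str) -> list[tuple[str, str]]:
        return list(self.planted[gid])

    def to_json(self, path) -> None:
        def enc(obj):
            if isinstance(obj, dict):
                return {("|".join(k) if isinstance(k, tuple) else str(k)):
                        enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (dt.date,)):
                return obj.isoformat()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        cfg = asdict(self.config)
        cfg["start_date"] = self.config.start_date.isoformat()
        payload = {
            "config": cfg,
            "females": enc(self.females),
            "gregariousness": enc(self.gregariousness),
            "dyad_effects": enc(self.dyad_effects),
            "planted": enc(self.planted),
            "alpha": enc(self.alpha),
            "year_starts": enc(self.year_starts),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def null_config(base: SyntheticConfig) -> SyntheticConfig:
    """Copy of ``base`` with no planted preferences and no dyad-level
    latent effects: the only structure left is gregariousness
    heterogeneity, the regime in which preferred-associate calls should
    occur at roughly the nominal upper-tail rate."""
    return replace(base, preferred_fraction=0.0, preference_effect=0.0,
                   dyad_effect_sd=0.0)


def _ar1_step(prev: np.ndarray, rho: float, sd: float,
              rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros_like(prev)
    innov = rng.normal(0.0, sd, size=prev.shape)
    return rho * prev + math.sqrt(max(0.0, 1 - rho ** 2)) * innov


def generate(config: SyntheticConfig,
             rng: np.random.Generator | None = None
             ) -> tuple[ScanTable, SyntheticTruth]:
    """Generate a multi-year scan dataset plus its ground truth.

    Deterministic given ``config.seed``; the returned ScanTable passes the
    full I/O validation and its alpha schedule / roster round-trip through
    the CSV writers unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    truth = SyntheticTruth(config=config)
    roster: dict[str, Individual] = {}
    cols: dict[str, list] = {k: [] for k in
                             ("date", "scan_time", "group_id", "focal_id",
                              "focal_activity", "neighbours")}
    alpha_spells = []
    end_date = config.start_date + dt.timedelta(
        days=YEAR_DAYS * config.n_years - 1)

    times = [f"{h:02d}:{m:02d}" for h in range(8, 15) for m in range(0, 60, 10)]

    for gi in range(config.n_groups):
        gid = f"G{gi + 1}"
        alpha_id = f"{gid}-SB1"
        roster[alpha_id] = Individual(
            id=alpha_id, sex="M",
            birth_date=config.start_date - dt.timedelta(days=365 * 18),
            residency=[ResidencySpell(gid, config.start_date, None)],
            is_potential_alpha=True)
        alpha_spells.append(AlphaSpell(gid, config.start_date, end_date,
                                       alpha_id))
        truth.alpha[gid] = alpha_id
        truth.year_starts[gid] = [
            config.start_date + dt.timedelta(days=YEAR_DAYS * y)
            for y in range(config.n_years)]

        next_fid = 1

        def new_female(entry: dt.date) -> str:
            nonlocal next_fid
            fid = f"{gid}-F{next_fid:02d}"
            next_fid += 1
            roster[fid] = Individual(
                id=fid, sex="F",
                birth_date=entry - dt.timedelta(
                    days=365 * 14 + 200 * (next_fid % 5)),
                residency=[ResidencySpell(gid, entry, None)])
            return fid

        active = [new_female(config.start_date)
                  for _ in range(config.n_females)]
        g_val = {f: rng.normal(0.0, config.gregariousness_sd)
                 for f in active}
        all_pairs = [canonical_dyad(a, b) for i, a in enumerate(active)
                     for b in active[i + 1:]]
        n_plant = round(config.preferred_fraction * len(all_pairs))
        plant_idx = rng.choice(len(all_pairs), size=n_plant, replace=False)
        planted = {all_pairs[int(i)] for i in plant_idx}
        truth.planted[gid] = sorted(planted)
        e_val = {p: rng.normal(0.0, config.dyad_effect_sd)
                 for p in all_pairs}

        truth.females[gid] = {}
        truth.gregariousness[gid] = {}
        truth.dyad_effects[gid] = {}

        for y in range(config.n_years):
            y_start = truth.year_starts[gid][y]
            if y > 0:
                # AR(1) drift of latent structure
                ids = sorted(g_val)
                g_arr = _ar1_step(np.array([g_val[i] for i in ids]),
                                  config.persistence,
                                  config.gregariousness_sd, rng)
                g_val = dict(zip(ids, g_arr))
                pairs = sorted(e_val)
                e_arr = _ar1_step(np.array([e_val[p] for p in pairs]),
                                  config.persistence,
                                  config.dyad_effect_sd, rng)
                e_val = dict(zip(pairs, e_arr))
                # turnover at the year boundary: emigrant replaced by an
                # immigrant with fresh latent parameters (never planted)
                for f in list(active):
                    if rng.random() < config.turnover_prob:
                        spell = roster[f].residency[-1]
                        roster[f].residency[-1] = replace(
                            spell, exit=y_start - dt.timedelta(days=1))
                        active.remove(f)
                        newf = new_female(y_start)
                        active.append(newf)
                        g_val[newf] = rng.normal(
                            0.0, config.gregariousness_sd)
                        for other in active:
                            if other != newf:
                                p = canonical_dyad(newf, other)
                                e_val[p] = rng.normal(
                                    0.0, config.dyad_effect_sd)

            truth.females[gid][y] = sorted(active)
            truth.gregariousness[gid][y] = {f: float(g_val[f])
                                            for f in sorted(active)}
            truth.dyad_effects[gid][y] = {
                p: float(e_val[p]) for p in sorted(e_val)
                if p[0] in active and p[1] in active}

            month_len = YEAR_DAYS / 12.0
            order = sorted(active)
            rate = {f: config.scans_per_female_year * math.exp(
                        rng.normal(0.0, config.scan_dispersion)
                        - config.scan_dispersion ** 2 / 2)
                    for f in order}
            for f in order:
                others = [o for o in order if o != f]
                eta0 = np.array([
                    config.baseline_logit + g_val[f] + g_val[o]
                    + (config.preference_effect
                       if canonical_dyad(f, o) in planted else 0.0)
                    + e_val[canonical_dyad(f, o)]
                    for o in others])
                for month in range(12):
                    n_m = rng.poisson(rate[f] / 12.0)
                    if n_m == 0:
                        continue
                    day0 = int(round(month * month_len))
                    day1 = min(int(round((month + 1) * month_len)),
                               YEAR_DAYS)
                    days = rng.integers(day0, day1, size=n_m)
                    a_present = rng.random(n_m) < config.alpha_presence_prob
                    p = inv_logit(eta0[None, :]
                                  + config.alpha_effect
                                  * a_present[:, None].astype(float))
                    near = rng.random((n_m, len(others))) < p
                    t_idx = rng.integers(0, len(times), size=n_m)
                    act_idx = rng.choice(len(_ACTIVITIES), size=n_m,
                                         p=_ACTIVITY_P)
                    for s in range(n_m):
                        nbs = [others[k] for k in range(len(others))
                               if near[s, k]]
                        if a_present[s]:
                            nbs.append(alpha_id)
                        cols["date"].append(
                            y_start + dt.timedelta(days=int(days[s])))
                        cols["scan_time"].append(times[t_idx[s]])
                        cols["group_id"].append(gid)
                        cols["focal_id"].append(f)
                        cols["focal_activity"].append(
                            _ACTIVITIES[act_idx[s]])
                        cols["neighbours"].append(tuple(sorted(nbs)))

    import pandas as pd

    df = pd.DataFrame({
        "date": pd.to_datetime(cols["date"]),
        "scan_time": cols["scan_time"],
        "group_id": cols["group_id"],
        "focal_id": cols["focal_id"],
        "focal_activity": cols["focal_activity"],
        "neighbours": cols["neighbours"],
    })
    df = df.sort_values(["group_id", "date", "scan_time", "focal_id"],
                        kind="stable").reset_index(drop=True)
    # anchor: pin each group's first and last scans to the first and last
    # simulated days, so analysis windows align with simulated years and
    # the final year is a complete window
    for gid in df["group_id"].unique():
        gidx = df.index[df["group_id"] == gid]
        df.loc[gidx[0], "date"] = pd.Timestamp(truth.year_starts[gid][0])
        df.loc[gidx[-1], "date"] = pd.Timestamp(
            truth.year_starts[gid][0]
            + dt.timedelta(days=YEAR_DAYS * config.n_years - 1))
    df = df.sort_values(["group_id", "date", "scan_time", "focal_id"],
                        kind="stable").reset_index(drop=True)

    table = ScanTable(df, roster, validate=False)
    return table, truth


def alpha_schedule_for(truth: SyntheticTruth) -> AlphaSchedule:
    cfg = truth.config
    end = cfg.start_date + dt.timedelta(days=YEAR_DAYS * cfg.n_years - 1)
    return AlphaSchedule([AlphaSpell(gid, cfg.start_date, end, aid)
                          for gid, aid in sorted(truth.alpha.items())])


def write_dataset(table: ScanTable, truth: SyntheticTruth, outdir) -> None:
    """Write scans.csv / roster.csv / alpha_schedule.csv / truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_scans(table, out / "scans.csv")
    write_roster(table.roster, out / "roster.csv")
    write_alpha_schedule(alpha_schedule_for(truth), out / "alpha_schedule.csv")
    truth.to_json(out / "truth.json")
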