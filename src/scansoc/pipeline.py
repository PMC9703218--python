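"""End-to-end analysis runner.

Stages: read scans + roster -> (derive alpha schedule from agonistic
records via Elo if no schedule is given) -> 365-day windows per group ->
association networks per window and stratum -> permutation null model ->
alpha-present/absent cosine similarity -> year-over-year consistency
table and statistics -> per-group and pooled summary report.

All randomness flows from the single run seed through named substreams
(one per group-window in sorted order, one for the consistency
bootstrap), so re-running an identical configuration reproduces
report.json byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consistency import (InsufficientDataError, alpha_similarity_report,
                          build_consistency_table, consistency_stats)
from .elo import alpha_schedule as derive_alpha_schedule, read_agonistic
from .io import (AlphaSchedule, ConfigurationError, ScanTable,
                 read_alpha_schedule, read_scans, write_alpha_schedule)
from .network import (AssociationNetwork, build_windows, count_dyads,
                      networks_to_frame, no_female_scan_fraction)
from .nullmodel import (PermutationConfig, null_to_frame, permute_events,
                        summarize_null)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    scans: str
    roster: str
    alpha_schedule: str | None = None
    agonistic: str | None = None
    outdir: str = "scansoc_out"
    window_days: int = 365
    n_perm: int = 1000
    swaps_per_event: int = 10
    interval: tuple[float, float] = (2.5, 97.5)
    lags: tuple[int, ...] = (1, 2, 3)
    n_boot: int = 1000
    min_overlap_days: int | None = None
    seed: int = 0
    elo_k: float = 100.0
    elo_start: float = 1000.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "interval" in data:
            data["interval"] = tuple(data["interval"])
        if "lags" in data:
            data["lags"] = tuple(data["lags"])
        return cls(**data)


def _summary_stats(strengths: list[float]) -> dict:
    arr = np.asarray(strengths, dtype=float)
    if arr.size == 0:
        return {"mean": None, "sd": None, "min": None, "max": None, "n": 0}
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min": float(arr.min()),
        "max": float(arr.max()),
        "n": int(arr.size),
    }


def run(config: RunConfig,
        table: ScanTable | None = None,
        schedule: AlphaSchedule | None = None) -> dict:
    """Execute the full pipeline; returns the report dict and writes
    edges.csv, null.csv, cosine.csv, consistency.csv, stats.json,
    report.json and run.log under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if table is None:
        table = read_scans(config.scans, config.roster)
    if schedule is None:
        if config.alpha_schedule:
            schedule = read_alpha_schedule(config.alpha_schedule)
        elif config.agonistic:
            events = read_agonistic(config.agonistic)
            schedule, timeline = derive_alpha_schedule(
                events, table.roster, k=config.elo_k,
                start_rating=config.elo_start)
            write_alpha_schedule(schedule, outdir / "alpha_schedule.csv")
            timeline.to_csv(outdir / "elo_timeline.csv", index=False)
        else:
            raise ConfigurationError(
                "need alpha_schedule or agonistic records")

    windows = build_windows(table, config.window_days)
    complete = [w for w in windows if not w.partial]
    n_partial = len(windows) - len(complete)
    if n_partial:
        log.info("excluding %d partial trailing window(s)", n_partial)

    networks: list[AssociationNetwork] = []
    summaries_by_key: dict = {}
    null_frames = []
    for wi, w in enumerate(sorted(complete,
                                  key=lambda w: (w.group_id, w.window_index))):
        net = count_dyads(table, w, "all",
                          min_overlap_days=config.min_overlap_days)
        networks.append(net)
        rng = np.random.default_rng(
            [config.seed, 1_000_003, wi])  # per-window substream
        pc = PermutationConfig(n_perm=config.n_perm,
                               swaps_per_event=config.swaps_per_event,
                               seed=config.seed,
                               interval=config.interval)
        summ = summarize_null(net, permute_events(net, pc, rng=rng), pc)
        summaries_by_key[(w.group_id, w.window_index)] = summ
        null_frames.append(null_to_frame(net, summ, pc))

    networks_to_frame(networks).to_csv(outdir / "edges.csv", index=False)
    null_df = (pd.concat(null_frames, ignore_index=True) if null_frames
               else pd.DataFrame())
    null_df.to_csv(outdir / "null.csv", index=False)

    cosine_df = alpha_similarity_report(
        table, schedule, windows=complete,
        min_overlap_days=config.min_overlap_days)
    cosine_df.to_csv(outdir / "cosine.csv", index=False)

    cons = build_consistency_table(networks, summaries_by_key,
                                   lags=config.lags)
    cons.to_csv(outdir / "consistency.csv", index=False)
    try:
        stats = consistency_stats(cons, n_boot=config.n_boot,
                                  seed=config.seed, lags=config.lags)
    except InsufficientDataError as exc:
        log.warning("consistency statistics skipped: %s", exc)
        stats = {"error": str(exc)}
    (outdir / "stats.json").write_text(json.dumps(stats, indent=1,
                                                  sort_keys=True))

    # ---- report ------------------------------------------------------
    groups = sorted({w.group_id for w in windows})
    report: dict = {
        "meta": {
            "scansoc_version": __version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "window_days": config.window_days,
            "n_windows_complete": len(complete),
            "n_windows_partial": n_partial,
        },
        "groups": {},
        "pooled": {},
        "consistency": stats,
    }

    def _block(gids: list[str]) -> dict:
        strengths = [float(s) for g in gids
                     for s in null_df.loc[null_df["group_id"] == g,
                                          "strength_obs"]] \
            if len(null_df) else []
        sub_null = (null_df[null_df["group_id"].isin(gids)]
                    if len(null_df) else null_df)
        sub_cos = cosine_df[cosine_df["group_id"].isin(gids)]
        cos_vals = sub_cos["cosine"].dropna()
        n_scans = int((table.records["group_id"].isin(gids)).sum())
        return {
            "n_scans": n_scans,
            "no_female_scan_fraction": no_female_scan_fraction(table, gids),
            "strength": _summary_stats(strengths),
            "n_dyad_years": int(len(sub_null)),
            "n_exceeds_chance": (int(sub_null["exceeds_chance"].sum())
                                 if len(sub_null) else 0),
            "n_preferred": (int(sub_null["preferred"].sum())
                            if len(sub_null) else 0),
            "cosine_mean": (float(cos_vals.mean()) if len(cos_vals)
                            else None),
            "cosine_sd": (float(cos_vals.std(ddof=1))
                          if len(cos_vals) > 1 else None),
            "mean_strength_alpha_present": (
                float(sub_cos["mean_strength_present"].dropna().mean())
                if sub_cos["mean_strength_present"].notna().any() else None),
            "mean_strength_alpha_absent": (
                float(sub_cos["mean_strength_absent"].dropna().mean())
                if sub_cos["mean_strength_absent"].notna().any() else None),
        }

    for g in groups:
        report["groups"][g] = _block([g])
    report["pooled"] = _block(groups)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    (outdir / "run.log").write_text(
        f"scansoc {__version__}\nseed={config.seed} n_perm={config.n_perm} "
        f"window_days={config.window_days}\n"
        f"finished={dt.datetime.now().isoformat()}\n")
    return report
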