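"""Calibration and power experiments for the permutation null model.

These drive the synthetic generator through the full analysis path
(generate -> window -> count -> permute -> classify) and score the
result against the generator's ground truth.  They back both the test
suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .network import build_windows, count_dyads
from .nullmodel import PermutationConfig, classify_group_year, permute_events, summarize_null
from .synth import SyntheticConfig, generate, null_config


def calibration_experiment(n_group_years: int = 200,
                           n_perm: int = 1000,
                           seed: int = 0,
                           scans_per_female_year: float = 500.0,
                           n_females_range: Sequence[int] = (5, 6, 7, 8),
                           ) -> dict:
    """False-positive calibration under the structureless null.

    Generates ``n_group_years`` single-year groups with heterogeneous
    gregariousness but no planted preferences and no dyad-level effects,
    runs the permutation test on each, and tallies the preferred and
    above-chance rates across all dyad-year decisions.  With the
    97.5th-percentile rule the preferred rate should sit a little below
    the nominal 2.5% upper-tail mass (the strict > rule and event
    discreteness both push it down).
    """
    ss = np.random.SeedSequence(seed)
    n_dyads = n_exceeds = n_pref = 0
    for i in range(n_group_years):
        nf = n_females_range[i % len(n_females_range)]
        cfg = null_config(SyntheticConfig(
            n_females=nf, n_years=1,
            scans_per_female_year=scans_per_female_year,
            turnover_prob=0.0, seed=None))
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        table, _truth = generate(cfg, rng=rng)
        window = build_windows(table)[0]
        net = count_dyads(table, window)
        pc = PermutationConfig(n_perm=n_perm)
        counts = classify_group_year(net, pc, rng=rng)
        n_dyads += counts.n_dyads
        n_exceeds += counts.n_exceeds
        n_pref += counts.n_preferred
    return {
        "n_group_years": n_group_years,
        "n_dyad_decisions": n_dyads,
        "n_exceeds": n_exceeds,
        "n_preferred": n_pref,
        "exceeds_rate": n_exceeds / n_dyads,
        "preferred_rate": n_pref / n_dyads,
    }


def recovery_experiment(deltas: Sequence[float] = (0.5, 1.0, 1.5),
                        n_replicates: int = 100,
                        n_perm: int = 1000,
                        seed: int = 0,
                        scans_per_female_year: float = 2000.0,
                        n_females: int = 6) -> dict:
    """Detection power for a single planted preferred dyad.

    For each preference effect delta (log-odds), generates replicate
    single-year groups with exactly one planted dyad and records how
    often the permutation test flags that dyad as a preferred associate.
    Detection should rise with delta.
    """
    ss = np.random.SeedSequence(seed)
    n_pairs = n_females * (n_females - 1) // 2
    rates: dict[float, float] = {}
    for d_i, delta in enumerate(deltas):
        hits = 0
        for r in range(n_replicates):
            cfg = SyntheticConfig(
                n_females=n_females, n_years=1,
                scans_per_female_year=scans_per_female_year,
                preferred_fraction=1.0 / n_pairs,  # exactly one dyad
                preference_effect=delta,
                turnover_prob=0.0, seed=None)
            rng = np.random.default_rng(ss.spawn(1)[0])
            table, truth = generate(cfg, rng=rng)
            (planted,) = truth.planted["G1"]
            window = build_windows(table)[0]
            net = count_dyads(table, window)
            pc = PermutationConfig(n_perm=n_perm)
            summaries = summarize_null(
                net, permute_events(net, pc, rng=rng), pc)
            if summaries[tuple(planted)].preferred:
                hits += 1
        rates[float(delta)] = hits / n_replicates
    vals = [rates[float(d)] for d in deltas]
    return {
        "deltas": [float(d) for d in deltas],
        "detection_rates": rates,
        "n_replicates": n_replicates,
        "monotone": all(a <= b for a, b in zip(vals, vals[1:])),
    }
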