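"""Network similarity and year-over-year consistency of associations.

Two questions are answered here.  First, are female–female association
patterns an artefact of both females staying near the alpha male?  The
association network built from scans where the alpha was within 5 m of
the focal is compared with the network from scans where he was not,
using cosine similarity of the aligned edge-weight vectors: 1 means the
two strata share the same association pattern, 0 means they share none.

Second, how consistent are dyadic associations across years?  Each
dyad-year observation is joined to the same dyad's score one, two and
three windows earlier and to top-partner indicators, producing the
long-format table on which lagged regressions can be fitted externally.
The module itself provides non-parametric summaries: lag-k Spearman
correlations with dyad-permutation p-values, and the top-partner repeat
rate against its chance expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AlphaSchedule, ScanTable
from .network import (AssociationNetwork, WindowKey, build_windows,
                      canonical_dyad, count_dyads, top_partner,
                      NoPartnerError)


class AlignmentError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class DyadVector:
    """Edge weights of one network laid out on an agreed dyad order."""

    dyads: tuple[tuple[str, str], ...]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.dyads) != self.weights.size:
            raise AlignmentError("dyad order and weights differ in length")
        if (self.weights < 0).any():
            raise ValueError("association weights must be non-negative")


@dataclass(frozen=True)
class CosineResult:
    value: float | None
    n_dyads: int
    degenerate: bool
    window: WindowKey | None = None


def align_networks(a: AssociationNetwork, b: AssociationNetwork
                   ) -> tuple[DyadVector, DyadVector]:
    """Lay both networks out on the union of their dyads; a dyad absent
    from one network contributes weight 0 there."""
    order = tuple(sorted(set(a.dyads) | set(b.dyads)))
    wa = np.array([a.dyads[d].strength if d in a.dyads else 0.0
                   for d in order])
    wb = np.array([b.dyads[d].strength if d in b.dyads else 0.0
                   for d in order])
    return DyadVector(order, wa), DyadVector(order, wb)


def cosine_similarity(a: DyadVector, b: DyadVector,
                      window: WindowKey | None = None) -> CosineResult:
    """cos(theta) = a.b / (||a|| ||b||), in [0, 1] for non-negative
    weights.  A zero-norm vector asserts nothing about similarity, so the
    result is degenerate (missing) rather than 0."""
    if a.dyads != b.dyads:
        raise AlignmentError("vectors are not aligned to the same dyad order")
    na, nb = np.linalg.norm(a.weights), np.linalg.norm(b.weights)
    if na == 0.0 or nb == 0.0:
        return CosineResult(None, len(a.dyads), True, window)
    value = float(np.dot(a.weights, b.weights) / (na * nb))
    return CosineResult(min(value, 1.0), len(a.dyads), False, window)


def alpha_similarity_report(table: ScanTable, schedule: AlphaSchedule,
                            windows: Sequence[WindowKey] | None = None,
                            min_overlap_days: int | None = None
                            ) -> pd.DataFrame:
    """Per group-window cosine similarity between the alpha-present and
    alpha-absent association networks, plus mean dyadic strength in each
    stratum.  Degenerate (zero-norm) strata are flagged and carry missing
    cosine values."""
    if windows is None:
        windows = [w for w in build_windows(table) if not w.partial]
    rows = []
    for w in windows:
        pres = count_dyads(table, w, "alpha_present", schedule,
                           min_overlap_days)
        absn = count_dyads(table, w, "alpha_absent", schedule,
                           min_overlap_days)
        va, vb = align_networks(pres, absn)
        cos = cosine_similarity(va, vb, window=w)
        mean_p = (float(np.mean([d.strength for d in pres.dyads.values()]))
                  if pres.dyads else np.nan)
        mean_a = (float(np.mean([d.strength for d in absn.dyads.values()]))
                  if absn.dyads else np.nan)
        rows.append({
            "group_id": w.group_id,
            "window_index": w.window_index,
            "window_start": w.start.isoformat(),
            "cosine": np.nan if cos.degenerate else cos.value,
            "n_dyads": cos.n_dyads,
            "degenerate": cos.degenerate,
            "mean_strength_present": mean_p,
            "mean_strength_absent": mean_a,
        })
    return pd.DataFrame(rows, columns=[
        "group_id", "window_index", "window_start", "cosine", "n_dyads",
        "degenerate", "mean_strength_present", "mean_strength_absent"])


# ---------------------------------------------------------------------
# year-over-year consistency table
# ---------------------------------------------------------------------

def build_consistency_table(networks: Sequence[AssociationNetwork],
                            null_summaries: dict | None = None,
                            lags: Iterable[int] = (1, 2, 3)) -> pd.DataFrame:
    """Long-format dyad-year table with lagged scores and top-partner
    indicators.

    ``networks`` are whole-group ('all' stratum) networks, one per
    complete window.  Two rows are emitted per dyad-window, one per
    member direction, so top-partner indicators (which are properties of
    a member, not of the dyad) can be modelled with two data points per
    dyad; ``dyad_year_id`` identifies the pair.  Lag columns are present
    only when both members were co-resident members in both windows.
    ``null_summaries`` maps (group_id, window_index) -> {dyad:
    NullSummary} and fills the ``preferred`` column when given.
    """
    lags = sorted(lags)
    by_key = {(n.window.group_id, n.window.window_index): n
              for n in networks}
    if len(by_key) < 2:
        warnings.warn("fewer than two windows: consistency table is empty")
        return _empty_consistency_frame(lags)

    tops: dict[tuple[str, int, str], str | None] = {}
    for (gid, wi), net in by_key.items():
        for m in net.members:
            try:
                tops[(gid, wi, m)], _tie = top_partner(net, m)
            except NoPartnerError:
                tops[(gid, wi, m)] = None

    rows = []
    for (gid, wi), net in sorted(by_key.items()):
        summ = (null_summaries or {}).get((gid, wi), {})
        for (a, b), dc in sorted(net.dyads.items()):
            lagged = {}
            for k in lags:
                prev = by_key.get((gid, wi - k))
                lagged[k] = (prev.dyads[(a, b)].strength
                             if prev is not None and (a, b) in prev.dyads
                             else np.nan)
            pref = summ.get((a, b))
            for member, partner in ((a, b), (b, a)):
                top_prev = tops.get((gid, wi - 1, member))
                row = {
                    "group_id": gid,
                    "window_index": wi,
                    "id_a": a, "id_b": b,
                    "member": member, "partner": partner,
                    "strength_t": dc.strength,
                    "is_top_t": tops[(gid, wi, member)] == partner,
                    "is_top_lag1": (np.nan if (gid, wi - 1) not in by_key
                                    or top_prev is None
                                    or member not in by_key[(gid, wi - 1)].members
                                    else top_prev == partner),
                    "preferred_t": (pref.preferred if pref is not None
                                    else np.nan),
                    "group_size": len(net.members),
                    "dyad_year_id": f"{gid}:{a}|{b}:{wi}",
                }
                for k in lags:
                    row[f"strength_lag{k}"] = lagged[k]
                rows.append(row)
    cols = (["group_id", "window_index", "id_a", "id_b", "member",
             "partner", "strength_t"]
            + [f"strength_lag{k}" for k in lags]
            + ["is_top_t", "is_top_lag1", "preferred_t", "group_size",
               "dyad_year_id"])
    return pd.DataFrame(rows, columns=cols)


def _empty_consistency_frame(lags) -> pd.DataFrame:
    cols = (["group_id", "window_index", "id_a", "id_b", "member",
             "partner", "strength_t"]
            + [f"strength_lag{k}" for k in lags]
            + ["is_top_t", "is_top_lag1", "preferred_t", "group_size",
               "dyad_year_id"])
    return pd.DataFrame(columns=cols)


def consistency_stats(rows: pd.DataFrame, n_boot: int = 1000,
                      seed: int | None = None,
                      lags: Iterable[int] = (1, 2, 3)) -> dict:
    """Non-parametric consistency summaries.

    Per lag k: Spearman correlation between a dyad's score and its score
    k windows earlier, with a permutation p-value obtained by shuffling
    the lagged column over dyad-year rows.  Top partners: the fraction of
    individual-years whose previous top partner (still co-resident) is
    again the top partner, against the chance rate E[1/n_partners].
    Requires at least 10 lag-1-paired dyad-year rows.
    """
    rng = np.random.default_rng(seed)
    dyad_rows = rows[rows["member"] == rows["id_a"]]  # one row per dyad-year

    out: dict = {"lag_correlations": {}, "top_partner": None}
    for k in sorted(lags):
        col = f"strength_lag{k}"
        if col not in dyad_rows.columns:
            continue
        sub = dyad_rows.dropna(subset=[col])
        if k == 1 and len(sub) < 10:
            raise InsufficientDataError(
                f"only {len(sub)} lag-1-paired rows (need >= 10)")
        if len(sub) < 10:
            out["lag_correlations"][k] = {"rho": None, "p": None,
                                          "n": int(len(sub))}
            continue
        x = sub["strength_t"].to_numpy(float)
        y = sub[col].to_numpy(float)
        rho = float(stats.spearmanr(x, y).statistic)
        hits = 0
        for _ in range(n_boot):
            perm = rng.permutation(y)
            r = stats.spearmanr(x, perm).statistic
            if abs(r) >= abs(rho):
                hits += 1
        out["lag_correlations"][k] = {
            "rho": rho,
            "p": (hits + 1) / (n_boot + 1),
            "n": int(len(sub)),
        }

    top = rows.dropna(subset=["is_top_lag1"])
    top = top[top["is_top_lag1"].astype(bool)]
    if len(top):
        repeat = float(top["is_top_t"].astype(bool).mean())
        chance = float((1.0 / (top["group_size"] - 1)).mean())
        out["top_partner"] = {"repeat_rate": repeat,
                              "chance_rate": chance,
                              "n": int(len(top))}
    return out
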