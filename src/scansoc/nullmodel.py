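"""Degree-preserving permutation null model for association networks.

The observed co-proximity events of a group-window are randomized by
repeated double partner-swaps: two events (a,b) and (c,d) are drawn
uniformly, one of them is flipped with probability 1/2, and the rewiring
(a,d), (c,b) is applied unless it would create a self-pairing.  Every
accepted swap preserves each individual's event-endpoint count and the
total number of events exactly, so the randomized networks hold every
female's gregariousness fixed while shuffling *who* she was near.

Each permutation sample restarts from the observed event list and applies
``swaps_per_event × E`` accepted swaps (E = number of events), giving
independent draws.  Permuted dyadic scores are computed with the observed
denominators (focal-scan counts are untouched by partner swaps).  Per
dyad, the mean permuted score is the expected association score and the
2.5th/97.5th percentiles bound the 95% interval; a dyad whose observed
score exceeds the mean was associating more than expected by chance, and
one whose observed score exceeds the upper bound is a *preferred
associate*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .network import AssociationNetwork, canonical_dyad


@dataclass(frozen=True)
class PermutationConfig:
    n_perm: int = 1000
    swaps_per_event: int = 10
    seed: int | None = None
    interval: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.swaps_per_event < 1:
            raise ValueError("swaps_per_event must be >= 1")


@dataclass
class PermutedSamples:
    """Permuted event counts: ``counts[s, k]`` is dyad k's event count in
    sample s, with dyads indexed by ``pair_index`` over ``members``."""

    members: tuple[str, ...]
    counts: np.ndarray  # (n_perm, n_members**2), canonical key lo*n + hi
    degenerate: bool = False

    def pair_key(self, a: str, b: str) -> int:
        n = len(self.members)
        ia, ib = self.members.index(a), self.members.index(b)
        lo, hi = min(ia, ib), max(ia, ib)
        return lo * n + hi

    def counts_for(self, a: str, b: str) -> np.ndarray:
        return self.counts[:, self.pair_key(a, b)]

    def as_maps(self) -> list[dict[tuple[str, str], int]]:
        """Per-sample dyadic N_ab maps (convenience for small instances)."""
        n = len(self.members)
        out = []
        for s in range(self.counts.shape[0]):
            m: dict[tuple[str, str], int] = {}
            nz = np.nonzero(self.counts[s])[0]
            for key in nz:
                lo, hi = divmod(int(key), n)
                m[(self.members[lo], self.members[hi])] = int(self.counts[s, key])
            out.append(m)
        return out


def _event_arrays(network: AssociationNetwork
                  ) -> tuple[np.ndarray, np.ndarray]:
    idx = {m: i for i, m in enumerate(network.members)}
    ea, eb = [], []
    for (a, b), dc in sorted(network.dyads.items()):
        ea.extend([idx[a]] * dc.n_ab)
        eb.extend([idx[b]] * dc.n_ab)
    return (np.asarray(ea, dtype=np.int32), np.asarray(eb, dtype=np.int32))


try:  # compiled chain; the numpy implementation below is the fallback
    from numba import njit

    @njit(cache=True)
    def _swap_chains_compiled(ea, eb, n_perm, target, seeds, n):  # pragma: no cover
        E = ea.size
        counts = np.zeros((n_perm, n * n), dtype=np.int64)
        max_iter = 1000 * target + 1000
        chunk = 8192
        for s in range(n_perm):
            np.random.seed(seeds[s])
            x0 = ea.copy()
            x1 = eb.copy()
            acc = 0
            it = 0
            pos = chunk
            rr = np.empty(chunk, dtype=np.int64)
            while acc < target and it < max_iter:
                if pos >= chunk:
                    # one 63-bit draw encodes (i, j, flip); the modulo
                    # bias is O(E^2 / 2^62), far below Monte-Carlo noise
                    rr = np.random.randint(0, 2 ** 62, chunk)
                    pos = 0
                r = rr[pos]
                i = r % E
                r //= E
                j = r % E
                f = (r // E) & 1
                pos += 1
                it += 1
                if i == j:
                    continue
                a = x0[i]
                b = x1[i]
                if f == 1:
                    c = x1[j]
                    d = x0[j]
                else:
                    c = x0[j]
                    d = x1[j]
                if a == d or c == b:
                    continue
                x1[i] = d
                x0[j] = c
                x1[j] = b
                acc += 1
            for k in range(E):
                lo = x0[k]
                hi = x1[k]
                if lo > hi:
                    lo, hi = hi, lo
                counts[s, lo * n + hi] += 1
        return counts

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _swap_chains(ea: np.ndarray, eb: np.ndarray, n_perm: int,
                 target: int, rng: np.random.Generator) -> np.ndarray:
    """Run ``n_perm`` independent swap chains, each accumulating ``target``
    accepted double swaps from the observed list.  Vectorized across
    chains; one candidate swap per active chain per iteration."""
    E = ea.size
    X = np.empty((n_perm, E, 2), dtype=np.int32)
    X[:, :, 0] = ea
    X[:, :, 1] = eb
    accepted = np.zeros(n_perm, dtype=np.int64)
    active = np.arange(n_perm)
    max_iter = 1000 * target + 1000
    it = 0
    while active.size:
        it += 1
        if it > max_iter:  # safety net; cannot trigger for swappable lists
            warnings.warn("swap chain stalled; returning partial mixing")
            break
        m = active.size
        i = rng.integers(0, E, size=m)
        j = rng.integers(0, E, size=m)
        flip = rng.integers(0, 2, size=m).astype(bool)
        a = X[active, i, 0]
        b = X[active, i, 1]
        c = np.where(flip, X[active, j, 1], X[active, j, 0])
        d = np.where(flip, X[active, j, 0], X[active, j, 1])
        ok = (i != j) & (a != d) & (c != b)
        if ok.any():
            ch = active[ok]
            X[ch, i[ok], 1] = d[ok]
            X[ch, j[ok], 0] = c[ok]
            X[ch, j[ok], 1] = b[ok]
            accepted[active] += ok
        active = active[accepted[active] < target]
    return X


def permute_events(network: AssociationNetwork, config: PermutationConfig,
                   rng: np.random.Generator | None = None
                   ) -> PermutedSamples:
    """Draw ``config.n_perm`` degree-preserving randomizations of the
    network's co-proximity events.

    Networks with fewer than three members or fewer than two events admit
    no partner swap; the samples then equal the observed data and the
    result is flagged degenerate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(network.members)
    ea, eb = _event_arrays(network)
    E = ea.size

    def _counts_from(X0: np.ndarray, X1: np.ndarray) -> np.ndarray:
        lo = np.minimum(X0, X1)
        hi = np.maximum(X0, X1)
        key = lo.astype(np.int64) * n + hi
        n_samp = key.shape[0]
        offset = np.arange(n_samp, dtype=np.int64)[:, None] * (n * n)
        flat = np.bincount((key + offset).ravel(), minlength=n_samp * n * n)
        return flat.reshape(n_samp, n * n)

    if n < 3 or E < 2:
        X0 = np.tile(ea, (config.n_perm, 1))
        X1 = np.tile(eb, (config.n_perm, 1))
        counts = (_counts_from(X0, X1) if E
                  else np.zeros((config.n_perm, n * n), dtype=np.int64))
        return PermutedSamples(network.members, counts, degenerate=True)

    target = config.swaps_per_event * E
    if _HAVE_NUMBA:
        seeds = rng.integers(0, 2 ** 32, size=config.n_perm, dtype=np.int64)
        counts = _swap_chains_compiled(ea, eb, config.n_perm, target,
                                       seeds, n)
    else:
        X = _swap_chains(ea, eb, config.n_perm, target, rng)
        counts = _counts_from(X[:, :, 0], X[:, :, 1])
    return PermutedSamples(network.members, counts, degenerate=False)


@dataclass(frozen=True)
class NullSummary:
    dyad: tuple[str, str]
    strength_obs: float
    association_exp: float   # mean permuted score
    lower: float
    upper: float
    exceeds_chance: bool     # obs > mean permuted score
    preferred: bool          # obs > upper percentile (and above chance)


def summarize_null(network: AssociationNetwork, permuted: PermutedSamples,
                   config: PermutationConfig
                   ) -> dict[tuple[str, str], NullSummary]:
    """Per-dyad expected score, percentile bounds and flags, computed from
    permuted event counts with the observed focal-scan denominators."""
    if permuted.members != network.members:
        raise ValueError("permuted samples do not match the network")
    lo_p, hi_p = config.interval
    out: dict[tuple[str, str], NullSummary] = {}
    for (a, b), dc in sorted(network.dyads.items()):
        if dc.denominator == 0:  # defensive: count_dyads drops these
            warnings.warn(f"dyad ({a},{b}) has zero denominator; excluded")
            continue
        strengths = permuted.counts_for(a, b) / dc.denominator
        exp = float(strengths.mean())
        lower, upper = (float(x) for x in
                        np.percentile(strengths, [lo_p, hi_p],
                                      method="linear"))
        obs = dc.strength
        exceeds = obs > exp
        out[(a, b)] = NullSummary(
            dyad=(a, b), strength_obs=obs, association_exp=exp,
            lower=lower, upper=upper, exceeds_chance=exceeds,
            preferred=exceeds and obs > upper)
    return out


class GroupYearCounts(NamedTuple):
    n_dyads: int
    n_exceeds: int
    n_preferred: int


def classify_group_year(network: AssociationNetwork,
                        config: PermutationConfig,
                        rng: np.random.Generator | None = None
                        ) -> GroupYearCounts:
    """Convenience tally of above-chance and preferred dyads for one
    group-window."""
    summaries = summarize_null(network, permute_events(network, config, rng),
                               config)
    n_exceeds = sum(s.exceeds_chance for s in summaries.values())
    n_pref = sum(s.preferred for s in summaries.values())
    return GroupYearCounts(len(summaries), n_exceeds, n_pref)


def null_to_frame(network: AssociationNetwork,
                  summaries: dict[tuple[str, str], NullSummary],
                  config: PermutationConfig):
    import pandas as pd

    rows = [{
        "group_id": network.window.group_id,
        "window_index": network.window.window_index,
        "window_start": network.window.start.isoformat(),
        "id_a": a, "id_b": b,
        "strength_obs": s.strength_obs,
        "association_exp": s.association_exp,
        "lower": s.lower, "upper": s.upper,
        "exceeds_chance": s.exceeds_chance,
        "preferred": s.preferred,
        "n_perm": config.n_perm,
        "seed": config.seed,
    } for (a, b), s in sorted(summaries.items())]
    return pd.DataFrame(rows, columns=[
        "group_id", "window_index", "window_start", "id_a", "id_b",
        "strength_obs", "association_exp", "lower", "upper",
        "exceeds_chance", "preferred", "n_perm", "seed"])
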