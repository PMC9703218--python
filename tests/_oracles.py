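"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and separate from the
library code paths it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def brute_dyad_counts(records, a: str, b: str):
    """Per-scan nested-loop recount of N_a, N_b, N_ab for one dyad."""
    na = nb = nab = 0
    for r in records:
        if r.focal_id == a:
            na += 1
            if b in r.neighbours_5m:
                nab += 1
        elif r.focal_id == b:
            nb += 1
            if a in r.neighbours_5m:
                nab += 1
    return na, nb, nab


def cosine_direct(wa, wb):
    """Direct-summation cosine, no vector algebra library calls."""
    dot = sum(x * y for x, y in zip(wa, wb))
    na = math.sqrt(sum(x * x for x in wa))
    nb = math.sqrt(sum(y * y for y in wb))
    if na == 0 or nb == 0:
        return None
    return dot / (na * nb)


def exact_expected_counts(members, events):
    """Exact expectation of each dyad's event count under the uniform
    distribution over ordered lists of loopless events with the observed
    per-individual endpoint counts (the stationary law of the
    double-swap chain).

    Enumerates every feasible count vector over dyads and weights it by
    its multinomial multiplicity E!/prod(m!).  Only viable for tiny
    instances.
    """
    deg = Counter()
    for a, b in events:
        deg[a] += 1
        deg[b] += 1
    E = len(events)
    pairs = [(a, b) for i, a in enumerate(members) for b in members[i + 1:]]
    total_w = 0
    exp = {p: 0.0 for p in pairs}
    for combo in itertools.product(range(E + 1), repeat=len(pairs)):
        if sum(combo) != E:
            continue
        d = Counter()
        for (a, b), m in zip(pairs, combo):
            d[a] += m
            d[b] += m
        if any(d[x] != deg[x] for x in members):
            continue
        w = math.factorial(E)
        for m in combo:
            w //= math.factorial(m)
        total_w += w
        for p, m in zip(pairs, combo):
            exp[p] += w * m
    return {p: v / total_w for p, v in exp.items()}
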