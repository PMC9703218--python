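# Methods

## Problem and data model

`scansoc` quantifies female–female association patterns in group-living
primates (it was designed around gorilla field protocols) from
instantaneous scan-sampling data.  The raw observation is a scan taken at
a fixed interval during a focal follow: the focal animal's identity and
activity, and the identities of all group members recorded within 5 m of
the focal.  A roster supplies each individual's sex, birth date (or an
explicit adulthood date) and group-residency spells.  Females are treated
as adult from the day they turn 10 years old; the boundary is inclusive,
which is the conventional reading of "aged ten years or older".

All dates are naive calendar dates.  Scan times are kept as metadata only.

## Association score

Scans are aggregated per group into consecutive 365-day windows anchored
at the group's first observation date (the window length is configurable;
365 days is the default unit of analysis).  Within a window, for an adult
female dyad (a, b):

    strength(a, b) = N_ab / (N_a + N_b)

with N_a, N_b the numbers of scans in which a (resp. b) was focal and
N_ab the number of scans in which the pair was within 5 m of each other
(one was focal, the other appeared in its neighbour list).  The score is
in [0, 1], symmetric, and is the weighted-degree edge value of the annual
association network.

Decisions where the field protocol leaves room:

- A scan with a focal and a neighbour counts one co-proximity event; if
  both directions occurred in simultaneous scans they count separately,
  consistent with the denominator containing both members' focal scans.
- Dyads enter a window's network only if both members were adult at the
  window start and co-resident for the full window by default
  (`min_overlap_days` relaxes this).  This avoids denominator distortion
  from mid-year immigrants.
- Dyads whose combined focal count is zero have an undefined score and
  are dropped with a warning.
- Trailing windows not fully covered by data are computed but flagged
  `partial` and excluded from permutation testing and cross-year
  consistency by default.

## Permutation null model and preferred associates

To ask whether a dyad associates more than expected given how gregarious
its two members are, the co-proximity events of each group-window are
randomized by double partner-swaps: draw two events (a, b) and (c, d)
uniformly, flip one with probability 1/2, and rewire to (a, d), (c, b)
unless that creates a self-pairing.  Accepted swaps preserve each
individual's event-endpoint count and the total event count exactly.
Each of the 1000 permutation samples (configurable) restarts from the
observed event list and applies `10 × E` accepted swaps (E = event
count); independent restarts make the samples exchangeable for
percentile estimation.  On small instances the chain's stationary law
matches the uniform distribution over loopless event lists with the
observed endpoint counts (checked against exhaustive enumeration in the
test suite).

Permuted scores reuse the observed denominators, since partner swaps do
not change focal-scan counts.  Per dyad, the mean permuted score is the
expected association score, and the 2.5th/97.5th percentiles (linear
interpolation between order statistics) bound the 95% interval.  A dyad
is *above chance* if its observed score strictly exceeds the mean, and a
*preferred associate* if it strictly exceeds the upper bound.  Preferred
is additionally required to be above chance; the two conditions coincide
except in the degenerate case of a dyad whose permuted score is zero in
almost all samples, where an interpolated percentile can fall below the
mean.  Networks with fewer than three members or fewer than two events
admit no swap; their samples equal the observed data (flagged
degenerate), so such group-years can never yield preferred dyads.  No
multiple-testing correction is applied across dyads.

## Alpha-male stratification and network similarity

Whether female associations are an artefact of both females staying near
the alpha male is tested by splitting scans into alpha-present and
alpha-absent strata and comparing the two resulting networks.  Presence
is operationalized as the alpha being recorded within 5 m of the focal at
that scan — proximity to the focal is the only alpha-location datum the
protocol collects.  This is a genuinely open definition (an "in view"
reading is plausible with richer data); the stratifier exposes a `mode`
hook for datasets that carry an in-view column.

Similarity is the cosine of the two aligned edge-weight vectors, laid out
on the union of dyads across the strata with absent dyads at weight 0:
1 means the strata share the same association pattern, 0 means none.  A
zero-norm stratum asserts nothing and yields a missing value rather than
0.  One cosine is computed per group-window and then averaged, rather
than pooling years first.

## Dominance and the alpha schedule

Alpha identity over time comes from an Elo hierarchy over decided
agonistic interactions among potential-alpha males, processed
chronologically: expected win probability 1/(1 + 10^((R_l − R_w)/400)),
winner gains k(1 − E_w), loser loses the same, so rating sums are
conserved.  Defaults k = 100 and start 1000 are the conventional
animal-behaviour parameterization; both are configurable.  Draws are
skipped with a log entry.  The alpha schedule is the piecewise-constant
top-rated resident male; ties break toward longer tenure then smaller
ID and are flagged.

## Year-over-year consistency

Each dyad-window observation is joined to the same dyad's score 1, 2 and
3 windows earlier (only when both members are members of both windows)
and to top-partner indicators.  Top partners are per-member properties,
so two rows per dyad-window are emitted (one per member) with a shared
dyad-year identifier; the exported table is column-compatible with
lagged mixed-model formulations, which users can fit externally.  The
package's own inference is non-parametric: lag-k Spearman correlations
with a permutation p-value (shuffling the lagged column across dyad-year
rows), and the top-partner repeat rate — the fraction of individual-years
whose previous top partner, if still co-resident, is again the top
partner — against the chance rate E[1/(group size − 1)].  Ties in
top-partner selection break toward the smaller ID and are flagged.

## Synthetic data generator

The generator emulates the structure of the field data so that every
stage is testable with known ground truth.  Per scan with focal f,
candidate neighbour j and alpha presence A ~ Bernoulli(p_A):

    P(j within 5 m of f) = logistic(beta0 + g_f + g_j + delta_fj
                                    + e_fj + beta_A A)

Gregariousness g_i and the dyad-level latent effect e_ij follow
stationary Gaussian AR(1) processes across years with coefficient rho.
Planted preferred dyads — a fixed set of `round(p_pref × n_dyads)` pairs
chosen at generation time — carry a constant log-odds bonus delta; the
year-to-year drift of the network is carried by g and e.  Focal effort is
scheduled round-robin by month with Poisson counts and a lognormal
per-female-year rate multiplier, reproducing realistically unbalanced
focal totals.  Turnover removes females at year boundaries (replaced by
immigrants with fresh latent parameters); mid-year transfers are not
generated, matching the full-window residency default.  The first and
last scans of each group are pinned to the first and last simulated days
so that analysis windows coincide with simulated years.

Defaults were chosen once to mirror the magnitudes reported for wild
gorilla groups: 6 females per group (observed annual means 4–6.6),
500 scans per female-year (observed totals imply roughly 370–630),
baseline co-proximity logit(0.035) with sigma_g = 0.3, sigma_e = 0.25 and
10% planted dyads at delta = 1.2 — yielding pooled mean association
scores near 0.05 and maxima near 0.17, as in the field data — alpha
effect +0.5 log-odds (associations somewhat elevated in the alpha's
presence), presence probability 0.5, persistence rho = 0.6 (associations
consistent on the order of two years), and 5% annual turnover.

What the generator does *not* emulate: spatial structure and transitivity
(neighbour draws are independent per candidate, so no triadic closure),
activity-dependent association, seasonal effort gaps, observation error
in identities, and within-day autocorrelation between consecutive
10-min scans.  Passing calibration and recovery tests therefore show the
statistical machinery is correct under a dyadic independence model, not
that field data meet those assumptions — in real scan streams,
autocorrelation between consecutive scans effectively reduces the number
of independent events, making the permutation test somewhat
anticonservative.

## Experiments the package ships

- **Calibration**: 200 single-year groups (5–8 females, cycled) from the
  structureless null (planted effects and dyad-level effects removed,
  gregariousness heterogeneity retained), 1000 permutations each.  The
  preferred rate across ~3700 dyad decisions should lie in [1.5%, 4.0%]:
  a little below the nominal 2.5% because of the strict inequality and
  event discreteness, with slack for the permutation-vs-generative null
  mismatch.
- **Recovery**: 100 single-year replicates per effect size delta in
  {0.5, 1.0, 1.5} log-odds, 6 females, 2000 scans/female-year, exactly
  one planted dyad; detection is the probability that dyad is flagged
  preferred.  Detection must reach 80% at delta = 1.5 and be monotone in
  delta.

These sizes keep the full suite and the reproduction script each within
a few minutes on a single core while leaving Monte-Carlo error well
inside the asserted margins.

## Numerical and reproducibility notes

- Percentiles use linear interpolation between order statistics
  (`numpy.percentile`, method "linear"); ties in permuted scores are
  handled by interpolation, not nearest-rank.
- The swap chain is implemented as a compiled per-sample loop (numba)
  with a vectorized numpy fallback; both draw (i, j, flip) from a single
  63-bit uniform per proposal (modulo bias O(E²/2⁶²), far below
  Monte-Carlo noise).
- All randomness descends from a single seed: the pipeline derives one
  substream per group-window in sorted order, so results are invariant
  to processing order, and re-running an identical configuration
  reproduces `report.json` byte for byte.
- Species/pooled aggregates are pooled dyad-year means, not means of
  group means.

## Known limitations

- The GLMM-based inference of the motivating analyses (dyadic
  association score models with crossed random effects) is out of scope;
  the exported tables are model-ready inputs instead.
- The minimum-reliable-window estimation that justifies the 365-day
  window elsewhere is not reimplemented; the window length is a
  parameter.
- The permutation null conditions on individual event totals only; it
  does not model day-level clustering of scans.
- Elo parameters are conventions, not estimates; optimized-k fitting and
  alternative dominance indices are not provided.
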