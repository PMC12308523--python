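# Methods

This note documents the models and procedures implemented in `pairwinter`,
the assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices that were genuinely open.

## Study design and calendar conventions

The pipeline targets a winter study design in which ~65 feeders with RFID
antennae run on 13 consecutive weekends (Saturday and Sunday only) of one
focal winter *t*, flanked by the breeding records of springs *t−1* and
*t+1*. Because sampling is weekend-only but behaviour unfolds in real time,
dates are coded as **experimental day**: weekend *k* (1-based) maps to days
7(k−1)+1 and 7(k−1)+2, so the second weekend is days 8 and 9 and the last
Sunday of a 13-weekend season is day 86. Season membership uses half-open
intervals [first Saturday, day after last Sunday); the boundary date of a
following season belongs to that season.

Visit timestamps are stored as real-valued seconds since midnight of the
season's first Saturday and snapped to the detector's 1/3-s scan grid.
Reading a visits file drops exact duplicates, merges re-reads of one tag at
one feeder within 1/3 s (on the raw time axis, before snapping), and
discards non-weekend detections; all three counts are logged.

## Flocking-event detection

Visits at one feeder on one day are partitioned into gathering events by a
one-dimensional Gaussian mixture over timestamps:

* candidate component counts 1..15 (configurable), EM initialised with
  quantile-spaced means, selection by BIC (AICc available);
* each visit is assigned to its maximum-responsibility component;
  components whose assigned time ranges interleave are merged, so events
  are disjoint, ordered intervals and every visit belongs to exactly one
  event.

Numerical choices worth knowing:

* **Variance floor 25 s²** (5-s SD). A gathering event spans tens of
  seconds; without the floor EM places near-singular spikes on tied or
  follower visits and the criterion oversplits small streams.
* **Component cap n/3**: a credible event needs a few visits.
* **Pre-segmentation at 30-min gaps.** No single event can span such a gap,
  so the stream is first split there and the mixture fitted per segment;
  the resulting partition is unchanged while EM cost stays linear in the
  day's event count. The criterion sweep stops after three consecutive
  non-improvements.
* The EM kernel is JIT-compiled with numba (pure-Python fallback included);
  a caller-supplied seed drives the single jittered restart used when a fit
  degenerates, so detection is deterministic given the seed.
* If EM fails outright, a 600-s gap rule segments the stream instead.

A gap-threshold oracle (`gap_oracle_events`) provides an independent
reference: on streams whose bursts are separated by at least ~10 times the
within-burst spread, the mixture partition and the gap partition agree (this
is tested over 100 randomized two-burst streams, and cross-checked once
against scikit-learn's mixture implementation).

`min_event_size` defaults to 1 (no event discarded); larger values fold
small events into their nearest neighbour rather than dropping visits, so
the partition property is preserved.

## Pair-status classification

Candidate dyads are all male–female pairs appearing in the breeding records
of spring *t−1* or *t+1* whose members both visited feeders in winter *t*
(dyads failing the presence test are `excluded_absent`). Rules, applied in
order:

1. **faithful** — bred together in both springs;
2. **divorcing** — bred together at *t−1*, and either both members were
   observed breeding with other individuals at *t+1*, or one re-paired
   while the other was unobserved at *t+1* but sighted strictly after the
   *t+1* breeding season (taken to end 30 June), so the split cannot be
   explained by death;
3. **new** — bred together at *t+1*, after each member bred with someone
   else at *t−1*, or one bred with someone else and the other is a juvenile
   (cohort year = *t−1*, no *t−1* breeding record);
4. **juvenile** — both members juveniles breeding together at *t+1* for the
   first time;
5. anything else — `excluded_unclear`. Within-season polygyny (a bird with
   two simultaneous partners) is also `excluded_unclear`, since the rules
   presume one partner per spring.

Statuses are exhaustive and mutually exclusive per dyad; one bird may
legitimately appear in two analysed dyads in a year (divorcing with the old
partner, new with the next). Pair identity is the sorted concatenation of
the two ids, so faithful pairs keep one id across winters. The whole rule
set is frozen as an enumerated truth table
(`pairwinter/data/pair_status_truthtable.csv`, 56 feasible three-season
histories with hand-assigned expected statuses) that the classifier must
reproduce exactly.

## Dyadic indices

For each analysed pair and experimental day on which at least one member
was detected (days with neither member detected yield no row, not a zero):

* **WA** (simple ratio index) = x/(m+f+x), pooling events across feeders
  within the day.
* **VAI** = (adj_m + adj_f)/(vx + vy), computed only inside the day's
  shared events. A visit is adjacent when the partner has a visit in
  [t−3 s, t): the window is closed at exactly 3.0 s, a simultaneous read
  does not count, and one partner visit may license several followers if
  each is within 3 s of it. This is the simplest literal reading of a
  "within 3 s after the partner" rule; no multiplicity constraint is
  imposed. With no shared events VAI (and mean flock size, the covariate
  for the VAI model) is undefined (NA) while WA is 0.
* **Preferred partner**: per focal bird and day, the opposite-sex associate
  (associate = shares ≥1 event that day) with the highest daily WA.
  Associates of unknown sex are never eligible, which implements the
  fallback to the best known-opposite-sex associate. Ties break by higher
  shared-event count, then lexicographic id, for determinism. Preference
  is deliberately asymmetric (A's top associate need not reciprocate).
* **Non-pair comparison**: long-format per bird-day WA and VAI with every
  same-day associate plus a partner indicator; the partner-vs-mean-of-others
  summary uses the plain mean over non-partner associates (other summaries
  would be easy to substitute; the choice is not critical and is not used
  by any headline result).

## Models and inference

Each index is modelled as a k/n binomial on the logit scale: WA with k=x,
n=m+f+x; VAI with k=adj_m+adj_f, n=vx+vy; preferred partner as binary.
Fixed effects are pair status (reference faithful), a polynomial in
standardized experimental day (degree 0 for the aggregate models, 1 or 2
for the over-time models; degree-1 vs degree-2 interactions are compared by
AICc = AIC + 2k(k+1)/(n−k−1)), status × day interactions, sex (preferred
model only) and standardized mean flock size (VAI model only, since
follower proportions shrink in larger flocks).

Day is z-scored before polynomial expansion (raw, not orthogonal,
polynomials on the standardized scale): only signs and orderings of
coefficients are scientific claims here, never magnitudes on a particular
day scale.

Overdispersion is available as a beta-binomial likelihood (one dispersion
parameter) and zero inflation as a single structural-zero intercept with no
covariates; both are fitted by direct likelihood optimisation started from
the binomial solution, with standard errors from the numerical Hessian, and
are adopted only when AICc prefers them. Pair-level dependence and year
structure are not modelled through random effects; instead they are
respected by the permutation scheme below, which treats whole pairs as
exchangeable units. This is a deliberate desk-scale replacement for a
mixed-model formulation.

**Permutation p-values.** For each term of interest,
p_perm = (1 + #{|coef_perm| ≥ |coef_obs|}) / (B + 1), B = 999 by default
(resolution floor 1/1000). Two schemes:

* *status-label*: pair-status labels are permuted across pair ids
  (stratified by season when present), keeping each pair's daily series
  intact — valid for terms involving status;
* *day-within-pair*: each pair's day values are shuffled within its own
  series — used for pure temporal terms, because under a status-label
  permutation the day main effect concentrates at the population-average
  slope rather than zero and the label test would be miscalibrated.

Permutation refits use the plain-binomial mean model via an in-package IRLS
(point estimates only; tested to match statsmodels to <1e-8); more than 20%
failed refits aborts with diagnostics. A datastream-flavoured alternative
(swapping individuals between same-day events and recomputing the indices)
ships as `datastream_permuted_tables` for sensitivity analysis; it is not
part of any default.

**Perfect separation.** If any status level's binary preferred-partner
responses are all 0 or all 1 (or the level is empty, flagged with a
distinct reason), the aggregate preferred-partner model is skipped — its ML
coefficient is infinite — and the over-time model is reported instead.

**Predicted curves.** Inverse-logit predictions per status on that status's
observed day grid, nuisance covariates at their means, 95% CIs by the delta
method on the link scale.

## Synthetic-data generator

The generator emulates the study design rather than any particular
dataset. Defaults (one focal winter):

| parameter | default | rationale |
|---|---|---|
| feeders × weekends | 65 × 13 | the emulated grid-and-weekend design |
| pairs (faithful/divorcing/new/juvenile) | 26/9/31/30 | per-season scale of the design's status composition |
| decoys (unclear/absent) + floaters | 6/6 + 20 (30% unknown sex) | exercise exclusion branches and the sex fallback |
| baseline joint-membership logit | −3.5 | yields daily WA ≈ 0.4 for faithful pairs, a plausible winter level |
| status offsets | 0 / −1.31 / −0.54 / −0.88 | divorcing < juvenile < new < faithful ordering |
| status slopes (per SD of day) | +0.24 / −0.26 / +0.14 / +0.29 | faithful rise, divorcing decline |
| status quadratics | 0 / 0 / −0.09 / +0.09 | n-shaped new, u-shaped juvenile |
| adjacency probability | 0.30 / 0.14 / 0.31 / 0.31 | divorcing deficit in within-event following |
| events per feeder-day | Poisson(3) | bursty but sparse visitation |
| visits per member | 1 + Poisson(1) | short feeding bouts |
| within-event SD | 40 s | far below inter-event gaps (~hours) |
| independent join probability | 0.02 | background co-occurrence noise |

Each pair joins an event jointly with probability
invlogit(baseline + offset + slope·z(day) + quad·z(day)²); otherwise
members (and floaters) join independently. Within joint events each base
visit triggers, with the status's adjacency probability, a partner follower
visit at +U(1/3 s, 3 s]. Timestamps are snapped to the 1/3-s grid. Flock
sizes and visit rates are therefore *emergent*; no field sets them
directly, which is why the configuration exposes visits-per-member and an
independent join probability rather than a flock-size distribution.

Histories are constructed so every non-decoy pair satisfies exactly its
status's defining rules: divorcing pairs include the
unobserved-but-sighted-later subtype at a configurable rate; re-pairing
partners and displaced former partners are winter-absent immigrants, so the
extra dyads they create are excluded for absence (mortality and immigration
thus arise naturally and are labelled in the ground truth). Ground truth —
per-pair status and trajectory parameters, per-bird sex/cohort/presence —
is serialized beside the data, and identical seeds give byte-identical
files.

`simulate_daily_table` additionally draws WA-style daily tables straight
from the binomial model (x ~ Bin(n, invlogit(η))), so logit-scale parameter
recovery can be tested exactly; it also powers the null simulations.

**What the generator does not emulate.** No spatial home ranges (feeder
choice is uniform), no weather or day-length effects, no within-day
routines, no observation error in breeding records, and status effects are
homogeneous within status (no pair-level random variation by default).
Passing tests therefore show that the pipeline recovers the structure it is
pointed at under the stated design — not that real data meet these
assumptions.

## Problem sizes used by the checks

The simulation studies run at the scales stated here as the package's
standard verification sizes: structure recovery across 20 seeds of the full
default design with B=999 permutations; type-I error over 200 no-effect
replicates at B=99 (where the rejection rate at α=0.05 must sit inside the
binomial 95% interval and the p_perm distribution must be uniform or
super-uniform); index/oracle agreement over 1,000 random event fixtures;
detector/gap-oracle agreement over 100 two-burst streams.

## Known limitations

* Random effects are replaced by permutation inference; absolute standard
  errors from the binomial fits understate uncertainty when pair-level
  heterogeneity is strong — use p_perm, or the beta-binomial variant.
* Event detection is feeder-local; simultaneous events at neighbouring
  feeders are never merged.
* The classifier's `excluded_unclear` bucket is a catch-all; it does not
  subdivide ambiguous histories further.
* Detections outside feeder operating hours are not filtered; if a
  deployment powers feeders down, filter upstream.
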