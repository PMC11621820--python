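# Methods

This note documents the models behind `totemlab`: what is simulated, which
parameters matter, what the synthetic data do and do not emulate, and the
design choices made where the design was genuinely open.

## The innovation landscape

The original game's recipe network is unpublished, so the package
constructs a *reference landscape* constrained to the published structure:
6 base resources, 27 tools, 115 logs (142 innovations), recipes of 1–4
ingredients (unordered, repetition allowed), at least 8 innovations before
the first log becomes producible, and 266,915 distinct totem contents
(multisets of 1–3 logs over 115 types — the count that identifies the
totem panel as admitting empty slots; a strict three-slot panel would give
260,130).

Construction is layered and seeded (`CANONICAL_SEED = 7`):

1. a **spine** — a strict chain of 8 tools, each consuming its predecessor
   plus a base resource — pins the minimum innovations-before-a-log to
   exactly 8 (the first log consumes the spine tip);
2. a handful of **primitive tools** craftable from the bare resources give
   the early game realistic discovery density;
3. remaining tools are wired randomly into whatever exists;
4. **basic logs** are gated behind tools whose dependency closure is at
   least 8 deep; **refined logs** each build on a recent log so complexity
   keeps rising; the three deepest logs share the strictly maximal
   complexity class.

Because every item has exactly one recipe, an item's minimal dependency
closure is its ancestor set in the recipe graph; `Item.depth` is the size
of that closure including the item itself (0 for bases).

**Log values.** Each complexity class receives a disjoint value range,
strictly increasing with complexity, and values are drawn without
replacement on a 0.5-point grid, so two same-complexity logs may (and
generally do) differ. Two calibration pins: the global minimum value is
50 (the printed minimum totem) and the apex trio is set so the best
three-distinct-log totem is exactly 1.3 × 5700 = 7410. The per-class
ranges themselves are a package choice — the original ranges are
unpublished — so 50/7410 is a calibration, not a claim of equivalence.

## Game engine

Time is discrete 1-second ticks; the session runner charges every agent
action its duration. The engine enforces: only produced items can be
combined (inherited recipes are knowledge, not items); rediscovery of an
already-produced item succeeds but adds nothing; failed combinations grow
a per-participant tried set that is never transmitted; totems require
produced logs and the best totem is kept; the final score is the best
totem plus 15 points per item first produced in the session. Every
session yields an append-only event log (JSON Lines / CSV round-trips)
from which all metrics and the final score can be recomputed; a replay
function re-executes the logged action sequence and must reproduce the
identical final state.

One scoring choice was genuinely open: whether the +15 bonus covers
reproduced inherited items or only first-in-lineage discoveries. The
package counts every item a participant produces for the first time in
their own session (inherited items still had to be physically remade);
the bonus basis is visible in the event log, so the alternative reading
can be recomputed from `discover` events if needed.

## Experimental designs

Extended individuals play one 50-minute session; repeated individuals
four 25-minute sessions inheriting their own record with practice carrying
over; chains four 25-minute generations, each a fresh participant
inheriting the predecessor's record; groups of 2 or 4 share one 25-minute
session on a common clock, observing each other's records as of the last
10-second sync point (never live state). Chains and repeated-individual
runs are the same process apart from the identity of the record's author
and the persistence of practice. Default cohort sizes mirror the study
(41 / 59 / 53 chains / 53 groups-of-2 / 38 groups-of-4). Dropout is not
simulated. Seeding is hierarchical (experiment → unit → session) and
recorded in the output manifest.

## Synthetic participants

The agent model is deliberately minimal: the functional forms are package
inventions chosen to carry the statistical structure the analyses assume,
calibrated once against the study's printed descriptive statistics.

* **Pacing.** A workshop action takes `base_action_seconds ×
  (total_actions + 1)^(−learning_exponent)` seconds (defaults 7.2 s,
  0.02), with mean-one lognormal noise per action (σ = 0.6). This yields
  ≈ 227 attempts per naive 25-minute session with a between-participant
  s.d. of ≈ 9.
* **Motivation.** Beyond 25 minutes of continuous play the attempt rate
  decays with half-life 2400 s, producing a ~16% drop in attempts between
  the halves of a 50-minute session. Separate 25-minute sessions never
  decay.
* **Reproduction.** Items known only from someone else's record require a
  record consultation (an observable monitoring event, 18 s) before the
  production attempt. Items the agent has produced before need only a
  brief own-record glance (2 s) and get faster with per-item practice,
  `(times_produced + 1)^(−0.55)`. Consequently a fourth-generation chain
  member spends ≈ 8 minutes re-creating an inherited record while a
  fourth-session individual needs ≈ 2 minutes despite a larger record —
  the acquisition-cost asymmetry the chain/individual comparison turns on.
* **Exploration.** The default draws uniformly from the untried portion of
  the feasible combination space (exact multiset sampling via the
  stars-and-bars bijection; the space is enumerated outright while small).
  A small "insight" share (2%) of draws is directed at currently
  satisfiable untried recipes, standing in for the visual and semantic
  cues human players exploit; without it a uniform searcher rarely passes
  the first recipe layer in 25 minutes. The paper-calibrated preset
  additionally anchors 70% of exploratory draws on the agent's most recent
  discovery (`exploration="complexity_biased"`). Anchoring is what makes
  redundancy emerge: co-present group members, who discover nearly the
  same items at nearly the same times, sweep the same small anchored
  subspaces, while a late chain generation anchors on deep items its
  predecessors never reached.
* **Monitoring in groups.** Spontaneous record checks arrive at 0.8 per
  minute per visible peer, and reproducing observed recipes adds further
  consultations, so monitoring counts rise with group size faster than
  with chain generation.

## What the synthetic data are and are not

The generator emulates the *structure* the analyses assume — session
timing, inheritance topology, learning curves, consultation costs,
motivation decay, redundant exploration — with magnitudes calibrated to
the study's printed summary statistics. It does not model human
participants: no individual differences beyond seeded noise, no memory
failure, no strategic demonstrator choice, no fatigue other than the
attempt-rate decay, no dropout. Passing tests therefore show that the
pipeline reproduces the documented directional trade-offs under these
mechanisms, not that the mechanisms are cognitively correct, and the
published human regression coefficients are not reproduction targets.

## Inference

All analyses are linear or binomial regressions with dummy coding and
95% central intervals on coefficient draws; contrasts are evaluated
draw-by-draw. Engines:

* Gaussian fixed-effects models use the exact conjugate
  Normal-inverse-gamma posterior with a weak normal prior scaled to 10
  standard deviations of the outcome (inverse-gamma(2, s²) on the error
  variance).
* Gaussian mixed models fit REML via `statsmodels.MixedLM`; the
  fixed-effect posterior is approximated by a normal at the estimates with
  the asymptotic covariance. When the mixed fit is singular (a boundary
  variance estimate), the fallback is OLS with cluster-robust covariance
  by the grouping factor — the dependence stays in the interval widths.
* Binomial models fit a GLM on (successes, failures) with cluster-robust
  covariance by unit when a unit random effect is specified; fits with
  non-finite or extreme coefficients raise a degenerate-design error
  rather than returning silent output.

Rows with missing outcomes (participants who never finished reproducing
their inheritance) are dropped with the count recorded in the fit
diagnostics. The zero-effect interval coverage of the conjugate engine is
93–97% over 500 replicates (checked in the acceptance suite), and mixed
and binomial engines recover known simulation truths within their
intervals.

## Problem sizes

The acceptance suite simulates 250 independently seeded units (60 chains,
60 repeated individuals, 60 extended individuals, 40 groups-of-2, 30
groups-of-4 — 800 participant-sessions) for the directional checks, and
uses 500 replicates for interval coverage; these sizes keep the full suite
in the tens of seconds while leaving all directional effects far beyond
their significance gates. Structural checks (censuses, totem-space
enumeration, oracle equivalences) are exact and run in seconds.
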