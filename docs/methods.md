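# Methods

## Zone geometry

Each turbine contributes three nested, yaw-independent vertical cylinders
in a local east–north–up (ENU) frame:

* **Rotor-swept zone (RSZ)** — radius = rotor radius + `rsz_buffer`
  (default 0 m, i.e. the physical sweep), altitude band from the minimum
  blade-tip height (maximum height minus the rotor diameter) to the
  maximum blade-tip height. For the two supported turbine classes this
  gives radius 50.5 m over 30.5–131.5 m, and radius 38.5 m over
  42–119 m. Manufacturer-reported tip heights are taken as authoritative
  even where they disagree with hub + rotor/2 by up to a metre (both
  canonical classes do); a one-time log warning notes the discrepancy.
* **Inner curtailment cylinder** — radius 150 m, height 200 m centred on
  the 80-m hub and clipped at ground, i.e. altitudes 0–180 m.
* **Outer curtailment cylinder** — radius 350 m, height 400 m, clipped:
  0–280 m.

All cylinder boundaries are closed (`<=`). Geographic coordinates are
projected with an equirectangular tangent-plane projection about the
turbine-layout centroid (`x = R·Δλ·cos φ₀`, `y = R·Δφ`, R = 6,371 km);
over a sub-20-km facility the distortion is centimetres, and the
projection inverts exactly, which the tests exploit. Terrain is treated
as flat in synthetic mode (altitudes above local ground); when real
turbine tables carry per-turbine ground elevations, track altitudes above
sea level should be referenced to them by the caller.

Time to collision is the smallest `t ≥ 0` at which the straight-line
extrapolation of the current position and velocity enters the RSZ,
obtained by intersecting the horizontal circle-crossing quadratic with
the altitude-band interval. The constant-velocity extrapolation (velocity
from the backward difference of the last two 1-Hz points) is a documented
stand-in for whatever predictor a deployed detection system uses; an
independent brute-force ray-stepping oracle at 0.01-s resolution verifies
the closed form in the tests.

## Track processing

Tracks are time-sorted per track id; duplicate timestamps are dropped,
tracks with fewer than two points or a median sampling interval outside
[0.2 s, 5 s] are rejected with a logged count, and altitudes below −10 m
are clipped to 0 with a warning (between −10 and 0 they are clipped
silently as sensor noise).

When two camera units track the same bird simultaneously — time ranges
overlap, and positions at timestamps matched within 1 s lie within 50 m
(median over matches) — the points from the unit with the greater mean
3-D line-of-sight distance to the bird are dropped within the overlap and
the remainder merged. Pairs are examined in sorted (unit, track) order so
three-way overlaps resolve deterministically, and the operation is
idempotent.

An **approach** is membership of a turbine's inner curtailment cylinder at
one or more points. The default interprets "within 150 m" as
inner-cylinder membership (horizontal ≤ 150 m *and* altitude within hub
± 100 m), since that cylinder is what defines the data filter
operationally; `approach_mode="horizontal_only"` switches to pure
horizontal distance for sensitivity analysis. **Entry** (y = 1) is any
point of the whole track inside that turbine's RSZ — necessarily also an
approach, since the RSZ is geometrically contained in the inner cylinder.
A track near k turbines yields k approaches (separate Bernoulli trials);
the month key is the calendar month (UTC) of the first in-cylinder point.
The eagle-classification confidence gate (max point confidence ≥ 0.90) is
applied per track, not per point, to avoid fragmenting tracks. Points are
not interpolated between samples: the data are discrete 1-Hz samples and
the synthetic generator guarantees label fidelity at that resolution.

## Curtailment rule

Evaluation order per observed point: confidence gate → outer-cylinder
gate → inner-cylinder trigger (always curtail) → time-to-collision
trigger (TTC ≤ 10 s). One event is recorded per (track, turbine) pair —
the first trigger — because the analysis uses events as filters rather
than durations. The default criteria are the post-change operating values
(150/350 m radii, 10 s); the earlier, stricter regime is expressible by
constructing a different `CurtailmentCriteria`.

## Risk model and sampler

The two-way random-effects formulation keeps random main effects *and*
the interaction; `include_main_effects=False` gives the interaction-only
reading. No sum-to-zero constraints are imposed: the location split
between `mu` and the effect vectors is identified only through the
zero-mean priors, as is standard for this formulation, so convergence is
monitored on the identified quantities — `mu`, the variance components,
and every observed-cell probability `p_tm` — rather than on individual
effects. "Uniform priors for means and variances" is honoured literally:
`mu ~ U(−10, 10)` and each *variance* (not SD) `σ² ~ U(0, 25)`, vague on
the logit scale; both ranges are configurable.

The sampler is Metropolis-within-Gibbs over blocks (`mu`; `alpha`;
`beta`; `gamma`; variances):

* Effect vectors are updated coordinate-wise with vectorised random-walk
  proposals — the Bernoulli likelihood factorises over turbines, months
  and cells, so per-coordinate acceptance is exact. Data enter through
  per-cell sufficient statistics (n, Σy), making iteration cost
  proportional to the number of observed cells (~700), not observations.
* Variances are drawn by exact Gibbs from their truncated inverse-gamma
  conditionals (`InvGamma(k/2 − 1, ss/2)` restricted to the prior range)
  when the conditional shape is positive; a Metropolis step on the exact
  conditional density covers the small-k corner.
* Likelihood-invariant translation moves propose shifting `mu` by δ and
  an entire effect vector by −δ (accepted on the prior ratio alone),
  which decorrelates the weakly identified location split and is the main
  reason the grand mean mixes well.

Step sizes adapt toward ~30% acceptance in windows of 50 iterations
during burn-in only, then freeze, preserving detailed balance for the
retained draws. Chains start from dispersed values: `mu` at the empirical
logit rate ± N(0, 0.5), effects at N(0, 0.1), variances near the middle
of the prior range. Each chain's generator is seeded from
`SeedSequence((seed, chain))`, so runs are bitwise reproducible.

Degenerate inputs: an all-0 or all-1 response logs a boundary-posterior
warning rather than failing; constant chains make the Gelman–Rubin
statistic undefined and return 1.0 with a warning. The Gelman–Rubin
statistic itself is the classic (non-split) form
`sqrt(((n−1)/n·W + B/n)/W)`; the tests cross-check it against an
independent implementation on stationary chains.

## Summaries and classification

The reference average is carried through the posterior as the
count-weighted mean `Σ n_tm p_tm / Σ n_tm` per draw — matching the
empirical entries/approaches definition, and reported alongside the
empirical scalar. Its credible interval under a uniform prior on a single
binomial rate is also available in closed form (Beta posterior
percentiles). Per-turbine summaries average a turbine's cell
probabilities over its *observed* months, unweighted (per-month likewise
over observed turbines); a count-weighted variant is a switch away.
Credible intervals are equal-tailed 2.5/97.5 percentiles of draws pooled
across chains. Probability of direction uses strict inequality, so exact
ties count as "not greater": with perfectly identical cells every pd is
0 — a documented degenerate case, irrelevant off a measure-zero set. No
multiplicity adjustment is applied across the ~700 cell comparisons;
hierarchical shrinkage is the only control, so isolated flags in null
settings are expected at up to the nominal 5%+5% rate (in practice
shrinkage pushes the false-flag rate far below that, which the null
calibration test quantifies).

## Synthetic data

The generator defines the study conditions: 110 turbines (44 of the
101-m-rotor class, 66 of the 77-m class) on a jittered 350-m grid
(≥ 250 m spacing), 11 calendar months starting 2018-05, camera units on a
coarser grid so every turbine is covered within 1,000 m, and staggered
monitoring starts (35% of turbines from month 1, 20% from month 3, 13%
from month 9, 32% from month 11) mirroring phased installation — which
also yields a realistic share of turbines observed only one month.
Ground-truth cell probabilities come from the model's own generative
structure with defaults `mu = logit(0.295)`, `σ_alpha = 0.3`,
`σ_beta = 0.1`, `σ_gamma = 0.5`: an overall entry rate near 0.295,
turbine-to-turbine variation of a few-fold, little systematic month
effect, and a cell-probability SD near 0.1. 10,000 approaches are
allocated to observed cells by a multinomial over log-normal intensities
(SD 1.0 on the log scale) to mimic unequal visitation; the per-cell count
distribution is an assumption and configurable.

Outcome labels are drawn first and 1-Hz paths constructed to realise
them: entering passes cut inside 60% of the RSZ radius at rotor altitude,
non-entering passes keep ≥ 10 m horizontal clearance from the swept
radius while dipping inside the inner cylinder, and 8.5% of tracks visit
a second turbine in the same month via a transit leg that climbs above
the 180-m inner-cylinder ceiling. Every candidate track is verified with
the *same* approach-detection code the pipeline uses — it must reproduce
exactly the intended approaches, labels and months against the full
layout — and re-drawn on failure (error after 100 attempts). Coordinates
are rounded to CSV precision (1e-6°, ≈ 0.1 m) *before* verification, so
the written fixture is exactly as verified. This construction makes the
ground truth exact by design, which the round-trip tests require.

What the generator does not emulate: behaviourally realistic eagle
movement (thermalling, wind response), terrain, detection dropouts,
classification-confidence structure, or real between-unit tracking
discrepancies (deduplication is exercised by dedicated crafted cases
instead). Passing tests therefore demonstrate the pipeline's geometric
and statistical correctness under controlled conditions, not field
performance of a detection system.

## Problem sizes and numerical choices

The default test and reproduction runs use the full study-scale design
(110 × 11, ~10⁴ approaches, 3 chains × 5,000 iterations), which fits and
summarises in well under a minute; unit tests use a 12-turbine facility.
Timestamps are POSIX seconds (UTC) and month keys `YYYY-MM`. Entry-time
tie-breaks take the smallest non-negative root; a point already inside a
cylinder has entry time 0; a stationary point outside has none.
Likelihood evaluations use the log-sum-exp-stable form of the Bernoulli
log-likelihood. The layout/effects/outcomes/tracks stages draw from
independent `SeedSequence((seed, k))` streams so that changing one stage's
randomness cannot silently shift another's.

## Known limitations

* Real-data mode expects altitudes already referenced to local ground.
* The deduplication rule drops the farther unit's points over the whole
  overlap window (not per point) and links tracks on a median-distance
  criterion; pathological crossing tracks from different units could in
  principle be merged.
* The interaction-only model variant shares the `gamma` label with the
  full model's interaction term but changes its meaning (it absorbs all
  cell-level structure).
* Curtailment replay is offline and per-point; it does not model spin-down
  time or energy loss.
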