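# Methods

`proxlog` couples a generative model of a proximity-logger deployment with
the analysis pipeline applied to its output. This note documents the model,
its parameters and defaults, the study conditions behind the reported
numbers, and the package's design choices and limitations.

## Radio propagation model

Expected RSSI between a source and a listener at distance `d` meters,
relative antenna angle `a`, and mount `m`:

```
E[RSSI] = rssi_at_ref + slope_per_log10m · log10(max(d, d_min_clamp))
          + mount_gain · [m = body]
          − orientation_penalty_max · (1 − exp(−d / orientation_ramp_m)) · |sin a|
```

Defaults are solved from the two distance anchors that define the network
thresholds (body mount, parallel antennae): RSSI 0 at 5 m and RSSI 40 at
0.1 m give `slope_per_log10m = −40/log10(50) ≈ −23.54` per decade and a
body-mounted reference of ≈ +16.46 at 1 m, split as `rssi_at_ref = 10.46`
(bare tag) plus `mount_gain = 6` (the amplification a body — animal or
saline balloon — adds; field tests find carcass and saline mounts
indistinguishable, so one additive gain covers both). With
`d_min_clamp = 0.02` m the curve tops out near +56 at physical contact,
matching the observed ceiling of 57.

The orientation penalty (`orientation_penalty_max = 19`,
`orientation_ramp_m = 0.13` m) reproduces the measured parallel-minus-
perpendicular gaps: ~1–3 units at contact, ~10 at 0.1 m, ~19 from 1 m
outward — the effect grows with distance and saturates.

Reported values are Gaussian-noised (`noise_sd = 2.2` at contact, growing
as `1 + d/10 m` so distant readings are noisier), rounded to integers and
clipped to the radio's reporting range −17..57. The floor matters
scientifically: beyond ~25 m a tag-tag pulse falls below −17 and is simply
never reported, and at 5–10 m the perpendicular-orientation readings pile
up on the floor — which is why those two distance bins are statistically
inseparable (below) while all closer bins resolve.

Receiver stations carry `receiver_gain = 14` RSSI units of antenna
advantage. The value is pinned by the system's stated geometry: tag-tag
reception dies near 25 m, yet receivers log tags out to 100 m, and
`E[RSSI](100 m) + 14` lands exactly at the −17 floor. A side effect is
that receiver readings of a tag at 10 m average near zero, which inflates
the coefficient of variation across stations at 10 m far above its 1 m
value — the inter-receiver variability pattern seen in field calibration.

## Movement model

Tags are assigned to nests on a grid (default 8 m spacing, two tags per
nest). Each tag follows an exactly-discretized Ornstein–Uhlenbeck walk
(relaxation `reversion_s = 10` s, stationary sd `home_sd_m = 1` m, hard cap
`max_home_range_m = 5` m) around an attractor that switches among four
states: home (the nest), **perch** (on the nest, sd 5 cm — nest mates
perching together produce body-contact RSSI ≥ 40), **visit** (another
tag's nest, sd 0.4 m — the social-contact generator, rate
`visit_rate_per_hour`), and **flight** (a random arena point, sd 2 m).
Headings are random walks with `heading_turn_sd = 0.1` rad/√s, slow enough
that antenna orientation persists across 20 s pulse slots; encounter
dropouts are then driven by distance rather than by orientation flicker,
which is what makes broken logs sit at systematically lower RSSI.

No movement statistics exist for the tagged birds, so this model is a
stand-in: it produces the right *radio* phenomenology (sustained close
contacts, mid-range intermittent detection, long separations) without
claiming behavioral realism. Real trajectories are continuous in time,
three-dimensional, and much faster in transit; the simulator moves
attractors discontinuously and samples positions every 5 s.

## Firmware emulation

One state machine per tag consumes time-sorted detections:

* pulses below the detection threshold (default 0 RSSI) are invisible;
* a first detection of a partner opens an encounter; each further
  detection updates min/max/sum; a gap of more than one pulse interval
  closes it with `end = last detected pulse` — so a one-pulse encounter has
  duration 0, and recorded duration is `last − first` with
  `n_pulses = duration/20 + 1`;
* at 300 s the log is saved and a new encounter opens at the next
  detection (the merge step below is the exact inverse);
* at most 30 concurrent partners (extras ignored until a slot frees) and
  300 logs in RAM; overflow drops the newest log, counted in
  `dropped_log_count`; a nightly download window (23:50) empties RAM;
* clocks drift (default 2 s/day), receivers broadcast their clock every
  15 min to tags in range, and a tag adopts the receiver time iff the
  receiver's clock was set more recently; after a reset the clock saver
  restores `last saved + period/2 + 2` s;
* past its battery life a tag keeps pulsing but resets at random times
  (mean `reset_interval_s = 600` s), wiping RAM; its tail logs are never
  downloaded. Partners keep logging it — the mechanism behind late
  one-sided logs.

The firmware timeout for ending an encounter is not documented for the
real hardware; one missed pulse slot is assumed here because it makes the
≤ 20 s merge rule the exact inverse operation and yields zero-duration
single-pulse logs, both of which the field data exhibit. The real tags'
"mean RSSI" arithmetic is likewise unknown; the exact arithmetic mean is
used.

## Log reconciliation

1. **Merge**: same-pair logs on one logger separated by ≤ 20 s (the pulse
   interval) are coalesced; pre-merge fragments are retained.
2. **Dyad calling**: per unordered tag pair, merged logs from both sides
   are swept in start order; logs whose closed intervals overlap (touching
   endpoints count — with integer seconds a half-open convention would be
   arbitrary) accrete into one record. Two disjoint B-side logs bridged by
   one A-side log become a single dyadic record with a fragmented B side —
   the broken-log topology. Records with one side only are singles;
   `n_encounters = n_dyadic + n_single` always.
3. **Broken**: a dyadic record where exactly one side is continuous and
   the other has ≥ 2 fragments with an internal gap > 21 s covered by the
   continuous side. **Staggered**: either end's overhang exceeds 21 s.
   The 21 s constants are kept distinct from the 20 s merge gap, as
   configured in the field workflow; with integer timestamps "> 21 s"
   means ≥ 22 s, a distinction that only matters for clock-drifted logs.
4. **Uptime restriction**: records must lie wholly inside the intersection
   of all tags' operational intervals (strict containment; straddling
   records are dropped).

Zero-duration logs are kept throughout — a single pulse with high RSSI is
a real close-proximity contact, and no minimum-duration filter is applied
by default.

The whole chain is verified against an independent brute-force oracle
(fix-point pairwise merging plus boolean transitive-closure matching) on
enumerated and randomized placements of up to 4 fragments per side.

## Calibration operations

`simulate_calibration` reproduces the standard trial design: 11 tag pairs
× distances (0, 0.1, 0.5, 1, 2, 5, 10 m) × 2 orientations × 3 replicates,
with a per-pair random intercept (sd 0.8 — inter-tag variability is low).
`fit_propagation` fits RSSI ~ distance × orientation linear mixed models
(random pair intercept, ML) in both meters-linear and log10-distance
parameterizations; the log model matches the simulator and its slope is
the recovery target. Slope recovery is assessed on trials generated with
the reporting floor lowered to −90 ("repeater-mode bench"): with the −17
floor in place the far perpendicular readings are censored and an
uncensored mixed model is not a consistent estimator (a censored-likelihood
model is beyond this package's scope). Median slope error over 50 designs
is ~1%.

`distance_bin_discriminability` compares every pair of distance bins with
Welch tests (Holm-adjusted) **and** an effect-size floor: bins are
*distinct* only if adjusted p < 0.05 and |Cohen's d| ≥ 0.6. The floor is
the operative part — with 66 readings per bin, p-values saturate, and what
matters for field use is whether the categories separate by a usable
margin. Under the defaults exactly one pair fails: 5 m vs 10 m, the upper
limit of distance discrimination. `infer_distance_bin` returns only the
coarse bin implied by the 40/0 thresholds plus a likelihood profile —
deliberately never a point distance, since RSSI–distance inversion is not
robust to orientation and environment.

## Reliability statistics

`reciprocity_stats` summarizes |side A − side B| for max/min/mean RSSI and
duration over dyadic records with paired t tests.
`fit_dyad_probability` is a logistic model of dyadic-vs-single outcome on
the combined record's max, min, mean RSSI and duration (encounters ≤ 300 s;
an optional time-window filter mirrors restricting analysis to early
logging hours). Longer and stronger encounters are more likely dyadic; in
this generative model the *duration* effect is robustly positive, while
the minimum-RSSI coefficient is not separately identified from the level
measures — the probability that a partner misses an entire encounter is
governed by its strongest pulses, so the conditional information sits in
the maximum/mean, and the combined-record minimum (pooling both sides'
pulses) is mechanically lower for dyads. This is a known, documented
divergence between the model family and field reports that attribute the
effect to the minimum.

`match_broken_logs` pairs each broken record with the unmatched unbroken
record closest in duration (ties to the earlier start);
`broken_vs_unbroken_summary` compares max/min/mean RSSI and the within-
record spread (max − min) between the matched groups with Welch tests and
Cohen's d. In simulation, broken records average lower RSSI on all three
level measures while the spread does not differ — dropouts happen where
tags are farther apart, not where RSSI varies more.

## Networks

Each reconciled record (dyadic counted once, single counted once)
increments its pair's edge weight when the record's combined maximum RSSI
clears the threshold. Density is the fraction of possible pairs with at
least one encounter. For thresholds t1 < t2 the t2 network is nested in
the t1 network edge-by-edge and weight-by-weight. Exports: edge-list CSV,
GraphML (node attributes such as sex preserved), symmetric matrix CSV —
all lossless round-trips. Layout/visualization is out of scope.

## Study conditions used for validation

* **Ideal colony** (`reciprocity_study`): 17 tags, one compressed hour,
  noiseless radio, detection threshold at the sensitivity floor, no drift,
  healthy batteries, arena diagonal < 4.1 m so that even perpendicular
  pairs stay above the reporting floor. Because pulse phases are
  unsynchronized, 100% dyadic reciprocity is achievable only when every
  tag hears every pulse; this condition isolates the pipeline, which must
  then produce all-dyadic, zero-broken, zero-staggered records.
* **Field-like colony** (`quality_study`): 14 tags on 7 nests, 3 h, default
  radio and 0-RSSI threshold. Sized so that one run yields ~2000 encounter
  records and ~80 broken dyads — enough for stable group comparisons while
  a 20-seed replication stays under a minute of compute. Its dyadic
  fraction (~34%) and broken share of dyads (~12%) land near field-reported
  magnitudes without being tuned to them.
* **Deployment layout** (`deployment_study`): 17 tags, 6–9 am / 5–8 pm
  windows, 60 × 36 m arena with 8 receivers — the end-to-end configuration
  for CLI runs.

Passing tests under these conditions show the pipeline's bookkeeping and
the model's qualitative structure are right; they do not certify the
movement model as barn-swallow behavior, nor the noise model as the true
433 MHz channel (real multipath fading is temporally and spatially
correlated; the simulator's noise is independent per pulse).

## Numerical and degenerate-input choices

Integer seconds everywhere in the core; ISO-8601 UTC only at the CSV
boundary. One master seed expands to fixed per-component seeds
(BLAKE2-derived, < 2^31), so stages are independently reproducible and
whole-run outputs are byte-identical under a fixed seed. Logistic fits
fall back to a small ridge penalty under complete separation (flagged in
the result); constant predictors are excluded with a warning; reciprocity
and matching operations signal empty or undersized inputs rather than
returning silent NaNs. Mean RSSI merging is pulse-count weighted; paired
t statistics on exactly identical sides are reported as t = 0, p = 1.
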