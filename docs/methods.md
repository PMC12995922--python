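# Methods

This note documents the model implemented in `standres`, the conventions
and numerical choices it makes, the default parameterization, and what the
shipped synthetic parameter bundle can and cannot show.

## Stand representation and time

Time advances in discrete 5-year steps; ages are stored in years and are
always multiples of 5.  A stand is a set of at most two age-homogeneous
cohorts, each with an age, an area share (shares sum to 1), and an origin
(`planting`, `gap_regeneration`, `salvage_replant`).  The older cohort is
*leading*; equal-age cohorts are merged (needed after a stand-replacing
disturbance of a two-cohort stand).  The canonical stand state used as
aggregation key is `(regime id, leading age, gap age)`, with bare soil and
"no gap cohort" coded as −1.  States are Markovian by construction: the
simulator's transition law depends only on this composition and the
regime.  Cohort origin and the accumulated growth-modifier history are
*not* part of the key — a deliberate coarsening that keeps the state space
small enough for dense sampling; its main effect is that states reached
via salvage replanting share value estimates with regularly replanted ones.

## Management scheduler

Deterministic and total on valid states:

* bare soil → plant the whole area (origin `planting`);
* any cohort at rotation age (default *u* = 85 a) → final harvest of its
  share, immediate replanting;
* a *single* cohort at exactly `age_gap` under a gap-cut regime → gap cut:
  the cohort's share splits into `1 − s_gap` (leading) and an age-0
  regeneration cohort of share `s_gap`.  A gap cut re-arms whenever the
  stand is again single-cohort (e.g. after a stand-replacing disturbance)
  and passes `age_gap`; a single cohort already older than `age_gap`
  receives none.  In the two-cohort steady state the regimes alternate
  compositions and the trigger never re-fires — by design, each regime is
  one constant rule;
* every other cohort → thinning per the yield table (possibly zero).

Within a step the order is: record state → disturbance draw → salvage and
replanting of failed cohorts → scheduled management → growth → ageing.
Hazards are evaluated at start-of-step ages, so a cohort can still be lost
in the step in which its final harvest is due.

## Disturbance model

Per-step hazards derive from a survival function:
`hz(a) = 1 − S(a+5)/S(a)`, undefined where `S` reaches 0 (rejected).  The
default functional form is Weibull, `S(a) = exp(−(a/scale)^shape)`; the
shipped coefficients (scale 90 a, shape 2.75) follow the published Weibull
shape for Norway-spruce stand survival and place survival to rotation age
near 0.43, the high-risk regime expected for spruce under hot-climate
conditions (the climate normals the curves refer to, T̄_w = 27.4 °C and
ΣP_wQ = 176 mm, are carried as provenance metadata only).  Empirical
coefficient sets load via `survival.yaml`.

One uniform draw per stand per step is shared by both cohorts; cohort *i*
fails completely iff `y ≤ hz_i`.  The shared draw intentionally correlates
failures: with an age-increasing hazard and a reduction factor ≤ 1 the
sheltered young cohort can only fail together with the leading one (the
*nested failure* property, enforced at classification time).  Non-leading
cohorts, being shorter than their age suggests, get
`hz_new = red_hz · hz` with

    red_hz = clamp(1 − (b0 + b1·(1 − s)) · Δage, red_min, 1),

defaults b0 = 0.002 /a, b1 = 0.004 /a, red_min = 0.3, where Δage is the
age difference to the leading cohort and *s* the young cohort's share.
The reduction grows with Δage and is stronger for smaller cohorts; leading
cohorts are never adjusted (gap-edge wind loading and edge-tree stability
gains are taken to cancel).  These coefficients are package defaults
satisfying the qualitative constraints, not empirical values.

Draw streams are seeded per run via `SeedSequence(seed, spawn_key=(run,))`
and reused across all regimes of a run (common random numbers), making
every disturbance counterfactually comparable across regimes and every
single run re-derivable in isolation.

## Growth and yield

A yield table (5-year grid, full stocking) supplies standing volume
(m³ ha⁻¹), mean DBH (cm), and the thinning removal of each step with its
DBH.  Tables starting at age 15 (the customary first entry) are completed
down to age 0 by linear interpolation of volume and DBH against (0, 0);
interpolated ages carry no thinning.

Gross volume production of a step is the standing-volume difference plus
the thinning removal booked at the end of the step; the removal is cut at
the step's end (it is standing wood until then, and is included in harvest
or salvage volumes if the cohort leaves early).  Cohort stock is tracked
as accumulated, modifier-adjusted increments, so competition effects leave
a persistent footprint in standing volume:

* suppression of the younger cohort:
  `m_supp = clamp(1 − (c0 + c1·(1 − s)) · Δage, m_min, 1)`,
  defaults c0 = 0.004 /a, c1 = 0.006 /a, m_min = 0.4;
* acceleration of the leading cohort after a gap cut:
  `m_acc = 1 + 0.5 · s_gap · max(0, 1 − years_since_gap/15)`.

Both multiply the step increment (and the step's thinning removal, keeping
mass balance exact).  DBH follows the cohort's chronological age
unmodified: tracking a separate "growth age" would add a hidden state
variable outside the aggregation key, and the price/cost functions are
smooth in DBH, so the simplification is second-order for valuation.

## Ecosystem-service valuation

Removals are valued as `volume · (price(dbh) − cost(dbh))`; salvage sells
at 74 % of price with 115 % of cost.  Planting costs are 2000 € ha⁻¹
(regular), 4000 (after salvage), 1000 (gap regeneration), scaled by the
replanted share.  Salvage credits the full pre-disturbance standing volume
at the degraded factors.  Gap-cut removals are valued at the leading
cohort's DBH at `age_gap`, scaled by `s_gap`.  The shipped price/cost
shapes (saturating price anchored at 92.47 € m⁻³ for DBH ≥ 45 cm;
mechanized-to-motor-manual cost curve) are synthetic defaults; empirical
systems load via `valuation.yaml`.

Carbon provision is the gross volume increment × 0.205 t_C m⁻³
(410 kg m⁻³ wood density × 0.5 carbon fraction; the identity is verified
at construction).  Harvests and disturbances create no negative carbon
provision in the default gross mode.

## Present-value estimation

`V_ES` at a state is the expected discounted provision sum (annual
compounding; financial rate 1.5 %/a, carbon 0.5 %/a).  The infinite
horizon is truncated at H = 1000 a, bounding the error for provisions
≤ M per step by `M (1+r)^−H / (1 − (1+r)^−5)` (≈ 2·10⁻⁵ of M at 1.5 %).
A moving window of length H rolls along each simulated series; each
admissible start (those with `t0 + H ≤` series end) yields one sample
tagged with the state occupied at the window start (the pre-event
composition — so a harvest step's sample belongs to the mature state whose
value it realizes, and the value path shows the sawtooth: rising with
stand age, peaking at harvest, resetting to the SEV).  Cash flows are
booked at their event step; carbon of a step's growth at the step's end.
Samples pool by state; states with fewer than `min_state_samples`
(default 30) samples are flagged `sparse` rather than silently trusted.
The t = 0 sample of each run (bare soil) is the run's SEV.

In the zero-hazard limit the estimator reproduces the Faustmann value
`Σ_cycle CF_t (1+r)^−t / (1 − (1+r)^−u)` within the truncation bound
(tested against an independent cash-flow oracle).

## Resilience assessment

The recovery threshold per ES is the unweighted mean of all baseline value
samples (time-and-run occupancy mean of the clear-cut value path) — it
lies strictly between the baseline SEV and the baseline peak value.

Disturbance events are classified by pre-state and failing cohorts:
(1) complete failure without regeneration; (2) complete failure of a
two-cohort stand; (3) failure of only the older cohort; (4) failure of a
leading cohort of gap-regeneration origin.  The partition is total for all
combinations reachable under nested failures; anything else raises.

Recovery times are measured on re-joined value paths (state → mean value).
Because the state recorded at the event step is still the pre-disturbance
composition, the recovery clock's relative time zero is the first
observation *after* the event (one step later); a path already at or above
the threshold there recovers in 0 years, otherwise the crossing is
interpolated linearly between the bracketing grid points.  Each event's
clock runs to its first crossing regardless of later disturbances.  Events
whose path never crosses before the truncated series end are *censored*:
counted, excluded from mean gains.  Only events early enough to have
post-disturbance observations inside the truncated value path
(t ≤ series − horizon − step) are assessed.

Counterfactual pairing per run takes the union of failure steps across a
gap regime and the baseline; a regime without its own failure at a paired
step contributes the (possibly zero) time its value path needs to reach
the threshold from that step.  Gain = baseline time − gap time; pairs with
a censored side are excluded from means and counted.

τ = (mean SEV difference vs. baseline) / (mean recovery-time gain).  The
`dominant` flag on `TradeoffResult` is τ ≥ 0, the sign convention of the
trade-off metric; note that with a *negative* mean gain a positive τ does
not indicate genuine dominance — the assessment summary therefore reports
SEV delta and mean gain separately, and the acceptance script counts
"no-trade-off" regimes as those with SEV delta ≥ 0 *and* positive gain.

## Default study conditions and problem sizes

| parameter | default | unit |
| --- | --- | --- |
| runs / series / step / horizon | 1000 / 2000 / 5 / 1000 | — / a / a / a |
| discount rates (financial, carbon) | 1.5, 0.5 | % p.a. |
| rotation age *u* | 85 | a |
| gap sizes × ages | {0.10…0.30} × {20, 40, 60} | — / a |
| survival Weibull (scale, shape) | 90, 2.75 | a, — |
| hazard reduction (b0, b1, red_min) | 0.002, 0.004, 0.3 | a⁻¹, a⁻¹, — |
| suppression (c0, c1, m_min) | 0.004, 0.006, 0.4 | a⁻¹, a⁻¹, — |
| acceleration (gain, window) | 0.5, 15 | —, a |
| growth curve V(a) = Vmax(1−e^{−ka})^p | 900, 0.025, 3 | m³ ha⁻¹, a⁻¹, — |
| carbon conversion | 205 | kg_C m⁻³ |

The test suite exercises scaled-down conditions (typically 4–40 runs,
1000–2000 simulated years, reduced regime grids) chosen so the whole suite
runs in seconds while still producing hundreds-to-thousands of disturbance
events where statistics are asserted.  `scripts/acceptance.py` runs the
full 16-regime experiment at 200 runs × 2000 a, a size at which regime
means are stable to a few percent between seeds.

## What the synthetic bundle shows — and does not

The shipped parameter tables are *synthetic*: they satisfy every
structural property of their empirical counterparts (monotone survival
with steeply age-increasing hazard, sigmoidal volume growth with
DBH-increasing margins, salvage/planting cost orderings) but none of their
numerical values.  Passing tests therefore demonstrate the correctness of
the machinery — conservation laws, closed-form limits, estimator
convergence, counterfactual bookkeeping — not empirical forest economics.
Two default-parameter outcomes deserve explicit mention:

* Under the default competition coefficients, gap regimes carry a
  substantial performance premium (SEV deltas down to ≈ −20 % financially,
  ≈ −7 % in carbon).  Their depressed value paths make mean *paired*
  recovery gains mostly negative, and in the carbon context many events
  never regain the baseline-derived threshold at all and are censored.
  Both are faithful consequences of the default suppression strength, not
  estimator artifacts; with milder (empirical) competition coefficients
  the structural benefit of surviving regeneration can dominate.
* The structural mechanism itself is visible regardless: early gap cuts
  (age 20) yield a consistently higher share of non-stand-replacing
  disturbances (types 3/4) than late ones (age 60), because regeneration
  shelters through more of the high-hazard ages.

## Known limitations

* At most two cohorts; no partial-cohort damage; disturbance is
  all-or-nothing per cohort — appropriate for small stands only.
* Climate enters only through the survival coefficients; no climate or
  price time series.
* The state key ignores cohort origin and modifier history (see above).
* Growth modifiers and hazard reduction use minimal linear forms; their
  coefficients are placeholders to be replaced by empirical fits.
* The recovery clock starts half a step after the disturbance draw (grid
  convention); this shifts all recovery times identically across regimes
  and cancels in gains.
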