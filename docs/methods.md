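# Methods

## Scope and intent

`ewsmon` implements an active-symptom-monitoring chain for psychosis relapse
detection: semi-random EMA prompting, a personalized weighted symptom score
with threshold alerting, adherence metrics, alert-performance evaluation,
and the design statistics of a two-arm feasibility trial.  No patient data
ship with the package; a synthetic trajectory simulator provides ground
truth for every end-to-end test.

## Prompting

"Semi-random" scheduling is implemented as stratified-uniform sampling: the
daily prompting window (default 09:00–21:00) is divided into
`prompts_per_day` equal bins and one instant is drawn uniformly in each bin.
A day whose draws violate the minimum spacing (default 2 h) is redrawn;
configurations where the spacing exceeds the bin width are rejected up
front, which guarantees the redraw loop terminates.  When the spacing
constraint is inactive the within-bin distribution is exactly uniform.
Supported cadence is 2–4 prompts/day with 2 as the default: deployed systems
of this kind have used twice-daily cues in routine care and four-daily in
validation studies, and twice daily is the routine-care setting this package
models.

The item catalogue has 12–14 branching items.  A branch child is presented
only when its parent's rating reaches the branch threshold (default: above
the scale minimum).  The shipped 12-item catalogue (7 psychotic, 5
dysphoric, two branch children) is *illustrative*: published descriptions
name the symptom domains but not the item list.

Ratings live on a 1–7 ordinal scale, mirroring the PANSS item range the
self-report items were validated against.  Because the instrument is a
continuous slider, ratings are validated against scale bounds but not
integrality; the simulator emits integers, while `scripted_stream` uses
fractional ratings to invert the weighting exactly.

## The EWS score

Relevance scores 0–3 per item encode the participant's relapse signature.
Tier shares are fixed at 20% / 30% / 50% of the total score for tiers
1 / 2 / 3, divided equally within a tier.  Design choices where the
published description is silent:

- **Combination rule** — weighted arithmetic sum. A convex combination
  keeps the score on the rating scale, which makes the baseline-relative
  thresholds interpretable.
- **Empty tiers** — shares renormalized proportionally across occupied
  tiers (e.g. `{A:3, B:2}` → 0.625 / 0.375), keeping Σw = 1 without
  arbitrarily inflating one tier.
- **Relevance-0 items** — still rated, weight 0.
- **Branch-skipped children** — imputed at the scale minimum for scoring:
  skipping encodes symptom absence, not missingness.
- **Partial prompts** — excluded from scoring by default (configurable).

The baseline is the mean score over the first 3 *calendar* days of
recording (not the first k datapoints) and is frozen thereafter.  An empty
baseline window raises an error rather than silently extending.

## Alert rules

Single-point rule: S(t) ≥ 1.40·B.  Two-consecutive rule: S(t) ≥ 1.25·B and
the immediately preceding completed score ≥ 1.25·B.  Further choices:

- Thresholds use ≥ ("rose to 40% higher" reads as attainment).
- "Consecutive" requires the two completed prompts to be ≤ 24 h apart
  (`max_gap`), so the pair rule cannot persist across multi-day gaps.
- Both points of a pair must lie after the baseline window; baseline-window
  datapoints neither trigger alerts nor qualify pairs.
- When both rules fire at one datapoint, the single-point rule is recorded.
- A 24 h refractory period suppresses follow-on alerts (care teams need a
  notification, not a storm); disable with `refractory_hours=None`.

`EWSDetector` packages this as fit/predict: `fit` derives the weights and
freezes the per-participant baseline, `predict` emits alerts for the
post-baseline stream.  The estimator implements
`get_params`/`set_params` and is `sklearn.base.clone`-compatible.

## Adherence

Counted at the prompt level (one completed prompt = one answered item set).
Acceptable adherence is a response rate strictly above 1/3, good strictly
above 1/2; comparisons use exact rational arithmetic so a rate of exactly
1/3 never classifies as acceptable through rounding.  Retention is
operationalized as ≥ 1 completed prompt in the final 7 days of the
monitoring period, since "continued use" has no standard definition.

## Simulator

Per item, latent severity = μ_i + prodrome ramp + AR(1) deviation
(deviation d ← ρ·d + ε, ε ~ N(0, σ²), stepped once per prompt), clipped to
the scale and rounded to integers at observation time.  AR(1) with clipping
is the simplest process with realistic short-range autocorrelation; stepping
per prompt rather than per unit time means ρ is interpreted per prompt
interval.

Prodromes: the number of events per participant is Poisson(λ); each event
draws an integer prodrome length uniformly in 1–5 days and a relapse day,
rejected until episodes do not overlap and start after the baseline week.
Dysphoric item means ramp linearly from prodrome onset to a peak amplitude
at the relapse day; psychotic means ramp identically but starting after a
lead (default 1 day, capped at the relapse day) — the two-stage dysphoric →
psychotic structure of the relapse signature.  The signal holds its peak
through the relapse day and ends a day later.  A lead longer than the
maximum prodrome length is a configuration error.

Missingness is completely at random at the prompt level (completion
probability `p_resp`, default 0.75); an optional severity-linked decrement
(`severity_missingness`) makes it informative, off by default.  A single
seed drives schedule, event placement, dynamics, and missingness through
independent substreams.

Defaults (84 days, 2 prompts/day, μ = 2, ρ = 0.6, σ = 0.5, λ = 0.5,
amplitudes 1.5 / 2.5) emulate a 12-week monitoring period in which roughly
40% of participants experience an episode — the order of magnitude
community teams document over 12 weeks.  λ and the amplitudes are
illustrative: true relapse base rates and prodrome magnitudes are not
published at this granularity.  What the simulator deliberately omits:
medication effects, measurement reactivity, time-of-day effects,
participant-specific response styles, and missingness bursts (device loss,
hospitalization).  Passing tests therefore show the chain is internally
correct and calibrated against its own generative model, not that these
thresholds would achieve the same operating characteristics on real
streams.

## Evaluation

No natural unit of analysis exists for "alerts versus documented
worsening", so the default partitions each participant's observation span
into consecutive 7-day windows: a window is positive if it overlaps any
episode (prodrome onset through the end of the relapse day — a prodromal
alert is the goal, so it counts as a true positive), and any alert in a
window claims it.  Confusion counts always satisfy tp+fp+fn+tn = number of
windows; undefined rates are NaN, never 0.  Episode-level sensitivity
(≥ 1 alert inside the episode, optionally extended backwards by a lead
margin) is provided as the alternative unit.  `ppv_from_rates` is the exact
Bayes identity PPV = se·π / (se·π + (1−sp)(1−π)) and reproduces any
confusion table's own PPV from its rates.

## Trial statistics

Power for the one-sided two-sample proportion test uses the
unpooled-variance normal approximation without continuity correction;
dropout inflates the total sample on the analyzable side
(n_arm = n_total(1−d)/2, left fractional).  At the design point (40% → 20%,
n = 72, d = 10%, α = 0.2 one-sided) this gives 83.1% power; the arcsine
approximation gives a similar figure, and both clear 80% — the package
standardizes on the normal approximation.  A 500k-replicate Monte-Carlo
simulation of the z-test agrees within 2 points.  Sample size is the
smallest even total whose power reaches the target (bisection on the
monotone power function).

The endpoint model is OLS of follow-up score on allocation group, site, and
baseline score; the group coefficient is the adjusted mean difference, with
95% CI and two-tailed p from the t distribution on residual df.  One-tailed
p is half the two-tailed p only when the estimate favors the active arm.
Listwise deletion is applied and reported; a single site drops the site
factor with a warning; group confounded with site raises.  An optional
group×site interaction is off by default.  A perfect fit (zero residual
variance) degenerates the t statistic; the implementation reports the
limiting p (1 for a zero estimate, 0 otherwise).  Under a null simulation
at n = 72 the one-sided α = 0.2 test rejects in 20.0% of 100,000
replicates (checked to ±0.5%).

## Numerical notes

- Weight conservation is exact: tier sums recovered by compensated
  summation (`math.fsum`) equal 0.50 / 0.30 / 0.20 to the last bit for
  every relevance assignment on ≤ 6 items.
- Threshold comparisons are plain floating-point ≥ on scores; scripted
  trajectories that hit a threshold exactly (e.g. 1.25·B with B = 2) are
  representable and alert deterministically.
- All timestamps are UTC; day windows are half-open `[start, end)` with day
  boundaries at UTC midnight.
- Problem sizes in the test suite (1,000-stream oracle equivalence, 100k
  null trials, 1,000-replicate effect recovery, 500k Monte-Carlo power
  replicates) were chosen to pin each statistic's Monte-Carlo error well
  below the tolerance being asserted.

## Known limitations

- Alert *delivery* (email/EHR integration), adaptive thresholds, and
  learned risk models are out of scope.
- The simulator's defaults are illustrative, not fitted to any cohort.
- The evaluation's windowing choice affects specificity materially; results
  should be reported with the unit of analysis stated.
- The ANCOVA handles a single follow-up timepoint; repeated-measures
  structures need mixed models, which this package does not provide.
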