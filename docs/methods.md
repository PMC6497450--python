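# Methods

## Model

Drinking is modelled as an embedded Markov chain with renewal structure.
At any moment the animal is in one of four states: non-drinking (1), or
drinking at a low (2), medium (3) or high (4) rate. Every drink returns
the chain to state 1 deterministically, so the sequence of drink states is
i.i.d. categorical with probabilities (P_l, P_m, P_h). The temporal
structure comes from five waiting-time laws, all with location fixed at 0:

| component | symbol here | family | support | default (cohort mean) |
|---|---|---|---|---|
| drink duration, low | `drink_low` | Weibull(k, λ) | (0, ∞) s | k = 1.03, λ = 16.62 s |
| drink duration, medium | `drink_medium` | Weibull(k, λ) | (0, ∞) s | k = 1.14, λ = 23.26 s |
| drink duration, high | `drink_high` | Weibull(k, λ) | (0, ∞) s | k = 1.23, λ = 8.63 s |
| bout span | `bout_length` | exponential | (0, ∞) s | λ = 141.45 s |
| intra-bout gap | `intra_bout_gap` | exponential | (0, 300) s | λ = 100 s (rate 0.01 /s) |
| inter-bout gap | `inter_bout_gap` | 300 s + exponential | (300, ∞) s | excess λ = 3000 s |

A Weibull shape k > 1 means the hazard of stopping a drink grows with its
length; k = 1 is the memoryless exponential. The cohort summary reports
exactly k = 1 for the bout span and both gap laws, so those are stored as
exponentials. The published intra-bout rate range 0.01–0.03 /s is held as
scales 33.3–100 s. The published inter-bout rate rounds to 0.00 /s, which
only bounds its scale from below (≳ 200 s); the package default is
3000 s, and the plausibility prior samples U[500, 8000] s — spanning the
sparse night-time gaps (≈ 9,000–45,000 s) visible in light drinkers'
inter-bout quantile plots. These inter-bout figures are this package's own
calibration choices, not published values.

A fixed probability `p_bout` decides whether each drinking event is a
multi-drink bout or a single drink. A bout draws a span L from
`bout_length` and emits drinks separated by intra-bout gaps
(rejection-sampled below 300 s) until the next gap + drink would exceed
L; at least one drink is always emitted, so short spans yield single-drink
bouts. Events are separated by inter-bout gaps, each at least the 300 s
lapse that defines a bout boundary. Each session day (default 22 h =
79,200 s) is an independent renewal: the day opens with a fresh inter-bout
delay rather than mid-drink, and drinks crossing the session end are
truncated there, keeping their rate. Nothing carries across days.

Simulated rates are the bin medians (0.383 / 0.798 / 1.376 mL/s); with
noise on they are Gaussian with sd equal to half the distance from the
median to the bin edge (0.1085, 0.151, 0.138 mL/s under default bins),
resampled — not clipped — until inside the bin, so the emitted rate class
always matches the drawn state. The high bin is unbounded above, so its
sd uses the lower edge by symmetry and draws are capped at 3× the high
median to exclude unphysical rates.

## Segmentation conventions

* Ticks occupy half-open intervals [t, t + resolution); a drink is a
  maximal run of positive increments whose quiet gaps are strictly less
  than 5 s. A gap of exactly 5 s separates drinks; a gap of exactly 300 s
  ends a bout (the verbal rules "less than 5 s" / "more than 300 s
  [ends it]" are taken literally at the boundary).
* The artifact filter removes drinks that are exactly 1 s long **and**
  hold ≤ 0.2 mL — the conjunction reading of the balance-noise rule; both
  conditions correspond to the instrument's resolution floor.
* The medium rate bin is closed, [0.6, 1.1] mL/s; low and high are open
  at the shared edges.
* Only ethanol records are modelled; water records are parsed and
  ignored (the merge refuses mixed-fluid input rather than silently
  pooling).
* Data-driven bin derivation smooths the rate sample with a Gaussian KDE
  (Silverman bandwidth unless given in mL/s), scans a 512-point grid for
  interior local minima by derivative sign change, and takes the two
  deepest. Fewer than two minima, or inconsistent resulting medians,
  falls back to the shipped edges with a `fallback` flag set.

## Estimators

* (P_l, P_m, P_h): fractions of classed drinks — the MLE.
* `p_bout`: the fraction of observed bouts containing ≥ 2 drinks. The
  convention treats a lone drink as the degenerate "no bout" outcome.
  Note the asymmetry with the generator: a simulated bout whose drawn
  span is short legitimately emits one drink, so the re-estimated
  `p_bout` is systematically below the generating one. The estimate
  describes the observable record (share of multi-drink bouts), which is
  the quantity the record can identify.
* Waiting times: maximum-likelihood Weibull (scipy, location pinned at
  0). Under the `auto` family policy the fit collapses to an exponential
  — whose MLE scale is the sample mean, exactly — when a likelihood-ratio
  test cannot distinguish the fitted shape from 1 at the 95% level
  (χ²₁ cut-off 3.84). This reproduces the reported behaviour that gap and
  bout-span fits come out exactly exponential.
* Inter-bout gaps all exceed 300 s by construction, so 300 is subtracted
  before fitting and the fitted law samples as 300 + draw.
* Any component with fewer than 30 events (e.g. intra-bout gaps in a
  record with no multi-drink bouts) is marked *absent* and filled with
  the cohort-mean default so the calibrated vector remains simulatable.

### What calibration does and does not recover

Round-trip experiments (simulate → re-calibrate) recover the transition
probabilities to ±0.03 and the three drink-duration Weibulls to ±10%
given ≳ 1,500 drinks per rate class. Three components are *not* expected
to match their generating values, for structural reasons:

* **Bout span.** The observed bout length is the realised drink/gap span,
  which the stopping rule keeps at or below the drawn span; single-drink
  events carry no span draw at all. The fitted value describes observed
  bouts, not the latent span law.
* **Intra-bout gap.** Gaps are fitted as an untruncated exponential (per
  the published fit-then-simulate order) although observations are both
  rejected at 300 s and length-biased by competition with the bout span;
  the fitted scale sits well below the generating one. The test suite
  checks it against an independent Monte-Carlo replay of the emission
  rule instead.
* **Inter-bout gap.** The shifted-exponential estimator is unbiased on
  uncensored draws, but gaps observed inside a finite session window are
  slightly short-biased (≈ scale/session, up to ~10% at an 8,000 s
  scale).

## Synthetic raw streams

`emit_raw_stream` emulates the acquisition chain: drinks are snapped to
the 0.1 s tick grid and spread over their ticks as 0.1 mL increments via
largest-remainder rounding, with the first and last tick pinned so the
observable support spans the drink. Volume is conserved to half a quantum
(0.05 mL) per drink; drinks below half a quantum still trip the scale
once (error ≤ 0.1 mL). The ground truth records the *observable* drinks —
computed by direct interval arithmetic on the emitted tick supports,
independent of the segmentation code path — so stream → segmentation
round trips can be asserted exactly. Optional distractors are balance
artifacts (1 s / 0.2 mL events placed with ≥ 5 s clearance) and an
independent water channel.

What the generator does **not** emulate: mechanical failures beyond the
1 s/0.2 mL artifact class, diurnal non-stationarity (night-time lulls),
age-related drift across months, and blood-ethanol kinetics. A green
round-trip therefore certifies the segmentation/calibration machinery on
model-faithful data, not robustness to those real-data features.

The plausibility prior (`sample_parameters`) draws shapes and scales
uniformly inside the published cohort min–max ranges, state probabilities
from a flat simplex, `p_bout` from U(0,1), and body weight from
U(7.5, 10.5) kg (bracketing the cohort means of 8.0–9.4 kg).

## Classification

Daily ethanol volume × 0.04 g/mL ÷ weight gives g/kg; days with zero
intake count in every denominator. Categories apply strict inequalities
with precedence VHD → HD → BD → LD. The VHD rule is the conjunction of
mean daily intake > 3 g/kg and > 10% of days over 4 g/kg. The binge (BD)
rule here is the intake-only surrogate — > 2 g/kg on > 55% of days, given
not HD/VHD — because the model does not output blood ethanol
concentration; the laboratory BD definition additionally requires a BEC
≥ 80 mg/dl event, so BD labels from this package are not directly
comparable to BEC-confirmed ones.

`replicate_classification` repeats simulation + classification with
seeds spawned from one master seed and tabulates category counts, plus
four-way and collapsed (heavy/non-heavy) agreement with a reference
label.

## Numerical choices

* All randomness flows through `numpy.random.Generator`; identical
  (parameters, config, seed) reproduce a series bit for bit.
* Exponential scales are fitted in closed form (sample mean); Weibull
  fits use scipy's MLE with `floc=0`. Constant (zero-variance) samples
  are rejected as degenerate rather than fitted.
* Rejection sampling (intra-bout gaps at 300 s; rate noise at bin edges)
  preserves the support invariants exactly; at default parameters the
  intra-bout rejection rate is e^(−300/100) ≈ 5%.
* Parameter files are schema-versioned JSON; scales may be declared as
  rates per second (`lambda_convention: "rate"`) and are inverted to
  seconds on read.

## Known limitations

* Stationarity within and across days is assumed; real animals drink
  less at night and drift with age.
* One shared set of drink-duration laws serves both in-bout and
  out-of-bout drinks; separate per-context fits are a possible extension.
* The bout-span and intra-bout-gap parameters are descriptive of the
  observed record rather than recoverable latent quantities (see above).
* Per-animal published parameters are not available; only cohort ranges
  inform the prior, so cross-study numerical comparisons are limited to
  range membership.
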