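# Methods

This note documents the models and procedures implemented in `vesselbird`,
the assumptions behind them, the parameters that matter, and what the
synthetic tests do and do not establish about real data.

## Geography and time

All distances are spherical great-circle (haversine) with R = 6371.0 km.
At the scales of this analysis (0.25-km distance bins, 50-km search
radius) the difference to an ellipsoidal geodesic is irrelevant.
Timestamps are handled internally as naive UTC; a fixed UTC+2 offset (no
DST) is applied only for diel summaries and day boundaries. Sunrise and
sunset come from the NOAA solar-position equations (fractional-year
Fourier series for declination and the equation of time, refraction
horizon at −0.833°); tests verify them within ±10 min against an
independently coded almanac-series ephemeris.

## Ethogram

* **VeDBA.** The static (gravitational) component of each axis is a 1-s
  centred running mean; VeDBA is the Euclidean norm of the three dynamic
  residuals, with per-second means attached. We interpret "1-s smoothing"
  as the static-estimation window (standard dynamic-body-acceleration
  practice); smoothing the VeDBA series itself is available as
  `smooth_output=True`.
* **Sitting on the water.** SIT iff 0.1 g ≤ per-second VeDBA ≤ 1.0 g *and*
  ground speed ≤ 2 m/s. The band is applied to per-second means. Ground
  speed per second is the mean speed of the *enclosing* 5-min GPS segment
  (piecewise constant). Interpolating between segment midpoints was tried
  and rejected: it bleeds flight speed into adjacent resting segments and
  vetoes genuine sitting around behaviour transitions.
* **Flapping.** 1-s windows of |Z| are described by their amplitude
  spectra (DC removed) and partitioned by k-means (k = 2, 10 restarts,
  fixed seed). The cluster with the higher mean peak amplitude inside the
  2–8 Hz wingbeat band is flapping — subject to two degeneracy guards:
  if the cluster peaks differ by <10% (relative), or the winning peak is
  below 0.2 g, no window is flagged. The absolute floor is needed because
  k-means always splits: a flightless stream (sensor noise, wave motion)
  would otherwise acquire flapping labels. Wingbeats carry ~1 g of dynamic
  acceleration, an order of magnitude above those sources, so the floor
  costs no sensitivity.
* **Gliding.** Non-flapping runs bounded on both sides by flapping and
  shorter than 30 s. Remaining time is SIT where the sitting rule holds,
  else OTHER. Labels are exhaustive and partition recorded time.
* **Daily summaries** (per local calendar day): flight time = summed FLAP
  + GLIDE durations (hours); the daily VeDBA sum is the sum over the
  day's 5-min intervals of the interval mean of per-second VeDBA. That
  summation convention yields magnitudes around 40 for a typical foraging
  day; it is an internal convention and the values are comparable only
  within this pipeline.

## VMS regularization

Native pings (1–2 h apart) are interpolated linearly in lat/lon onto a
global 10-min UTC grid (minutes ≡ 0 mod 10), so all vessels appear to
report simultaneously. Gaps longer than 4 h are not interpolated. The
grid speed is the chord speed of the bracketing native segment; the grid
ping also carries both bracketing native instantaneous speeds.

Activity classification is by gear-specific fishing-speed bands (trawl
1.0–4.5 kn, purse seine 0.0–2.5 kn, longline 3.0–7.0 kn; configurable;
gears without a band stay `unknown`). A grid ping is *fishing* only when
the chord speed **and** both bracketing native speeds fall inside the
band. Either condition alone fails in a characteristic way: chord-only
misclassifies segments spanning an activity transition, while
endpoint-only misses a steaming dash hidden entirely inside one native
gap (both endpoints slow, chord fast). On simulated fleets the mean
positional error of fishing-classified grid pings is well below 0.1 km,
versus several km for steaming pings — consistent with the published
accuracy scale of VMS interpolation, and the reason several downstream
steps trust only fishing pings.

## Interaction detection

* **Pairing.** For each bird fix at time *t*, the single grid instant in
  the half-open window [*t*−5′, *t*+5′) is selected (with a 10-min grid
  this guarantees exactly one ping per vessel); vessels farther than
  50 km are dropped.
* **Approach events.** Within each bird-vessel pair series, maximal runs
  of temporally consecutive fixes with strictly decreasing distance, a
  cumulative decrease ≥500 m, and ≥2 fixes. Runs starting beyond the
  30-km attraction distance are trimmed to their first fix inside (the
  cap bounds where attraction can begin; it is not an event veto). A
  stricter per-step ≥500 m reading is available via `per_step_drop=True`;
  neither reading is asserted as the original intent.
* **Distance profile.** Pairs are binned at 0.25 km from 0; each bin's
  mean of 100 × (SIT fraction of the fix's forward 5-min window). Bins
  with fewer than 110 pairs are dropped (scaled down proportionally when
  fewer than 4500 pairs are pooled, floored at 5). The pipeline restricts
  profile pairs to the trustworthy subset: fishing-classified pings,
  simultaneous fix/grid instants (a ping up to 5 min stale displaces a
  moving vessel by hundreds of metres — the same order as the interaction
  distance), and each fix's nearest vessel (the vessel the behaviour is a
  response to; pairs with farther vessels carry the attended vessel's
  sitting signal into the baseline). The profile extends to 5 km by
  default: far enough beyond any plausible interaction distance, short
  enough that the sitting baseline is flat (at larger ranges the
  commuting-route structure of the data makes the baseline trend and a
  two-segment model latches onto the trough).
* **Breakpoint.** The profile is fitted with the continuous two-segment
  model `y = β₀ + β₁·d + β₂·(d−ψ)₊` by profiling ψ over a grid of step
  bin/10; each candidate is an ordinary least-squares fit and the minimal
  RSS wins. Ties within numerical precision (relative 1e-8) resolve to
  the smaller breakpoint. A flat RSS profile (straight-line data) raises
  a degenerate-fit error. The 95% CI is a nonparametric percentile
  bootstrap over bins (default 1000 replicates, seeded); bootstrap rather
  than the delta method because it is distribution-free and exactly
  reproducible.
* **Validation.** Approaches whose minimum distance reaches inside the
  breakpoint (closed boundary) are interaction events. The pipeline
  additionally requires the minimum-distance fix to sit on a
  fishing-classified ping: interpolated steaming positions are too
  uncertain at the sub-interaction-distance scale to certify that a bird
  actually reached a vessel.

## Trips and group statistics

A trip opens at the first fix beyond the 2-km colony departure radius and
closes at the first fix back inside; both boundary fixes are included so
length integrals start and end at the colony, and trips need ≥3 at-sea
fixes (15 min) to suppress jitter loops. Completeness means both
boundaries observed. Trips of ≤3 days are "short" — the stratum used for
all group comparisons. Trip length is the summed haversine over
consecutive fixes; the maximum linear colony distance is taken over
fixes.

The four responses (daily VeDBA sum, daily flight time, trip length,
maximum colony distance) are modelled on sex × interaction status with a
REML linear mixed model (statsmodels `MixedLM`) with a random intercept
per bird. Wald F statistics (1 numerator df per term) are reported with
denominator df = observations − fixed-effect parameters; this bookkeeping
is documented, not asserted as the uniquely correct inference. Responses
failing a Shapiro–Wilk screen (α = 0.05 on residuals of the untransformed
fit) are log-transformed. Singular or non-convergent mixed fits fall back
to ordinary regression with a warning. Chi-square tests (gear preference
against fleet availability; sex × interaction occurrence) use no
continuity correction by default.

## Synthetic data generator

The generator emulates the study conditions: 5-min GPS, 25 Hz tri-axial
acceleration, native VMS pings every 60–120 min, a fleet with the
reported gear mix (76% trawl / 11% purse seine / 6% longline / 7% other),
a 30-km attraction distance and a true interaction distance d* = 1.28 km
by default. Defaults for quantities the system does not pin down were
chosen once on realism grounds: flight speed 10 m/s, search flight
8 m/s, sitting drift 0.2 m/s, GPS noise 30 m, steaming 8–12 kn,
haul-dominated fishing legs (6–10 h) with short steaming transits.

* **Vessels** follow leg-based tracks (quasi-linear hauls inside the gear
  speed band alternating with steaming transits) around operating centres
  12–40 km from the colony, outside a 4-km colony exclusion zone.
* **Birds** alternate colony stays (3–10 h) with trips: commute to a
  destination sampled 1–7 km from a fishing ground, hours of
  area-restricted foraging in 5-min blocks (sit vs search), return.
  Behaviour blocks are aligned to the GPS grid so each fix interval is
  behaviourally homogeneous, and positions are recorded at minute start
  so GPS segments line up with blocks.
* **Sitting probability** follows a linear ramp from `sit_prob_inside`
  (0.8) at a vessel's position down to `sit_prob_outside` (0.2) at d*,
  flat beyond — the sharp-rise-then-steady profile shape that the
  two-segment estimator assumes. (A hard step in probability at d* is
  not representable by a continuous two-segment mean and biases any such
  estimator upward by several bins; the ramp is the shape consistent
  with the estimation model.)
* **Scavengers** (a configurable fraction of birds, default 0.5) divert
  up to a few times per trip to the nearest main-gear vessel in a
  sustained fishing phase within the attraction distance, approach at
  full flight speed, and attend at 0.1–0.7 d* for 30–120 min — drifting
  while sitting, repositioning when the vessel pulls away, and taking
  off to rejoin once outside d* (so sitting-at-the-vessel strictly
  happens inside d* and the planted knee stays sharp).
* **Stand-off.** All birds keep ≥2.5 km from every vessel except during
  deliberate attendance. This separation is what makes "spurious
  interaction event" a well-defined concept in the ground truth: the
  margin above d* exceeds the measurement error of fishing-classified
  grid pings, so only deliberate attendance can be *measured* inside d*.
  Real non-scavenging birds plausibly avoid working gear, but the exact
  distance is a modelling convenience, not an observed constant.
* **Ground truth** records per-second behaviour labels, complete trips
  (metrics at fix resolution from exact positions), attendance episodes,
  and one planted approach/interaction event per attendance (the main
  descent, derived by applying the approach rule to the exact, noise-free
  joint geometry).
* **Accelerometer synthesis.** SIT = gravity plus a 1-Hz swell
  oscillation of 0.47 g amplitude (per-second mean VeDBA ≈ 0.3 g, inside
  the sitting band; below-band noise belongs to colony rest so the band
  rule is learnable); FLAP = a wingbeat sinusoid (4 Hz, 1 g) on Z;
  GLIDE/OTHER = near-static; Gaussian sensor noise (0.03 g) throughout.
* **Trip records for the group statistics** plant the reported foraging
  contrasts: daily flight 5.28 vs 6.22 h; daily VeDBA generated as a
  linear function of flight time (4.5 units/h) plus a direct interaction
  component, reproducing both the reported marginal contrast (≈6.14) and
  the strong flight-energy coupling; the female-by-interaction energy
  effect defaults to 12 units, sized a priori for ~90% detection power
  at the design's residual variance (~150 records over 50 birds, matching
  the reported degrees of freedom).

All randomness flows from one seed through fixed-offset substreams; a
fixed seed reproduces every stream byte for byte.

## Problem sizes

The default dataset is 10 birds × 4 days with 12 vessels (≈11.5k fixes,
≈100k bird-vessel pairs, ≈10⁸ accelerometer samples synthesized lazily
per bird). Parameter-recovery studies use 50 replicate profiles of 5000
pairs per true distance; the bootstrap uses 1000 replicates. These sizes
keep every stage deterministic and the recovery properties measurable
with tight Monte-Carlo error.

## What passing tests show — and what they don't

The synthetic generator is built from the same behavioural model the
pipeline assumes (ramp-shaped sitting response, attendance inside d*,
speed-filterable vessel activity). Passing recovery tests therefore
demonstrate *internal correctness* — the estimators recover what was
planted, through realistic measurement degradation (GPS noise, 1–2 h
native ping gaps, interpolation error, ping staleness, behaviour
misclassification) — not *external validity*. Real data add phenomena the
generator omits: weather-driven movement, rafting near the colony,
night-time behaviour changes, device saturation, non-Italian (untracked)
vessels, and birds attending steaming vessels, all of which can move a
real interaction-distance estimate.

## Known limitations

* The windowed-spectrum flapping classifier re-implements the *function*
  of the wavelet-based tool used in the original workflow; equivalence of
  the two spectral methods is not claimed.
* The daily VeDBA summation convention is internal; absolute magnitudes
  are not comparable across studies.
* The interaction-distance estimator assumes a single pooled breakpoint;
  per-gear or per-individual distances are not modelled.
* With sparse profile coverage just outside the breakpoint the bootstrap
  CI is conservative (wide to the right); the point estimate is the
  reliable quantity.
* The mixed-model denominator-df convention is simple subtraction;
  Satterthwaite or Kenward-Roger corrections are not implemented.
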