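# Methods

## Scope and data model

The package operationalizes a complete infant-actigraphy analysis chain
on a one-minute grid. A minute is half-open `[t, t+1)`; "a minute
asleep" is a minute whose scored state is SLEEP. Every night lives on an
*extended clock*: minutes since midnight of the night's calendar day,
with evening events before 04:00 mapped to `clock + 1440` so each
night's sequence (bedtime < onset < offset < get-up) is monotone. The
04:00 cutoff is a package choice; all observed infant bedtimes and
onsets in the cohorts this targets fall well before it. Midsleep is
reported on a linear minutes-past-midnight axis (it may dip a few
minutes negative for a pre-midnight midpoint) rather than wrapped into
[0, 1440): a modulo wrap at exactly 00:00 would split one continuous
quantity into two artificial clusters in any correlation analysis.

## Counts and scoring

Acceleration is band-pass filtered per axis at 3–11 Hz with a 4th-order
Butterworth applied forward–backward (zero phase), rectified and
compressed to 15-s bins (default statistic: sum of |filtered|, also
mean/max), fused across axes by sum of squares per bin, and summed four
bins to the minute. The filter realization and the bin statistic are
package choices behind a documented config; the band, bin width and
sum-of-squares fusion follow standard ankle-actigraphy practice.

The sleep/wake scorer is a windowed linear engine:

```
score = intercept − w_mean·MEAN − w_nat·NAT − w_sd·SD − w_log·ln(1+c)
```

with MEAN/SD over counts in a ±5-min window, NAT the number of window
epochs ≥ `nat_level`, and c the minute's own count; SLEEP when
score ≥ 0 (ties sleep, documented). All weights are non-negative, so
adding activity can only push toward WAKE (a monotonicity the tests
assert). Published infant coefficient sets can be supplied verbatim via
`ScorerConfig`; the package defaults (intercept 10, w_mean 0.03,
w_nat 0.4 at level 100, w_sd 0.005, w_log 0.3) separate low sparse
sleep-time counts from sustained waking movement on the count scale the
ingest stage produces. After the linear pass, minutes with activity at
or above `mean(activity) × 0.72` are forced to WAKE (the high/low
partition), then ordered run-length rules — fill wake islands < 5 min
inside sleep, then delete sleep islands < 5 min inside wake — are
iterated to a fixed point, which makes the whole smoothing operation
idempotent by construction. Rule order matters: filling before deleting
prevents brief forced-wake minutes from shredding the surrounding sleep
into deletable fragments. Edge windows are truncated, never padded;
MISSING minutes are never altered and act as run boundaries.

## Screening

Family thresholds (1 h partial-day, 3 h entire-day, 5 min
movement-count, 30-min clock-time windows) are counted within each
family's own window: the night window for partial-day/movement-count/
clock-time, the previous-offset→offset cycle for entire-day. The
diary-agreement cutoff (0.80 over minutes with a known diary state) is
a package stand-in for an unavailable appendix criterion and is exposed
prominently in the config. Family assignment of each variable follows
its analysis window (night durations → partial-day; daytime/24-h/SRI →
entire-day; activity-magnitude variables → movement-count; reported and
derived clock times → clock-time), except Sleep Efficiency, which is
kept in the entire-day family. Exclusion reasons are assigned in a fixed
precedence order so every excluded assessment carries exactly one
primary code.

## Variable definitions — edge rules

* Onset: first minute of the first ≥ 10-min sleep run at/after bedtime;
  if asleep at bedtime, the ongoing run's first minute (no length
  requirement — the infant was put down asleep). Offset mirrors this.
* "Exceeding 20 min" for naps is strict (a 20-min bout is not a nap);
  the ≥ 10-min onset/offset and ≥ 15-min wake-follow rules are
  inclusive, exactly as worded in the field's definitions.
* Longest Nocturnal Wake counts only wake runs followed by ≥ 15 min of
  sleep inside the sleep period; Nocturnal Wake Frequency counts *all*
  maximal wake runs (the follow rule is worded only for the longest-wake
  variable; a config flag applies it to the frequency too).
* Sleep Opportunity runs bedtime→get-up unless asleep at a boundary, in
  which case the boundary moves to onset/offset; with the half-open
  grid conventions TST + WASO = Sleep Period and efficiency ≤ 100 hold
  identically (asserted over randomized fixtures).
* Fixed-clock windows: day = 07–19 h of day *d*, night = 19 h(d)–07 h(d+1),
  24 h = 07 h(d)–07 h(d+1), so Day + Night = 24 h exactly.
* Variability slots are sample SDs (n−1) across ≥ 5 valid days; the SRI
  averages minute-of-day agreement over consecutive valid day pairs,
  excluding MISSING minutes from numerator and denominator.

## Composites

The assessment matrix (one row per participant-timepoint, 48 variable
slots plus age and sex) is completed by chained-equation predictive mean
matching (statsmodels `MICEData`); age and sex enter every conditional
model as covariates, approximating a two-level imputation in which the
participant level is carried by the strong cross-variable correlations.
Desk-scale defaults are m = 5 imputations × 10 iterations (configurable;
production analyses in this field run 100 × 100). The component count
comes from Horn's parallel analysis (observed correlation eigenvalues
vs the 95th percentile of 100 standard-normal surrogates). PCA is
computed on the correlation matrix — the 48 variables mix minutes,
counts, ratios and percentages, so covariance PCA is indefensible —
and rotated by promax (varimax → |loading|⁴ target → least-squares
Procrustes, power 4; verified against an independent reference
implementation to 10⁻³). Variables whose largest absolute pattern
loading is below 0.512 (a conventional cutoff for n > 100) are dropped
and the solution is refit on the retained set (a flag keeps the original
loadings instead). Each variable joins its max-|loading| component with
that loading's sign; a composite score is the unweighted mean of signed
z-scores. Components are labelled by the content of their assigned
variables and then *canonically oriented* on marker variables (WASO
positive for Sleep Activity, opportunity-variability for Sleep
Variability, nap count for Sleep Day, sleep offset for Sleep Timing,
sleep period for Sleep Night): an oblique rotation leaves each
component's global sign arbitrary, and anchoring it fixes the composite's
interpreted direction once and for all. Estimates across imputations are
pooled by Rubin's rules (with m = 1 passing through with a warning).
Where scores feed later models, scoring is done per imputation and the
model estimates pooled, not the matrices averaged first.

## Inferential layer

Age/sex effects are per-composite OLS (`score ~ exact_age + female`).
Stability uses Spearman correlations (mean ranks on ties; the
implementation is tested against rank-then-Pearson by construction)
with Bonferroni families of 15 (5 composites × 3 age pairs, threshold
0.05/15 ≈ 0.0033) and 10 (composite pairs). Within-subject stability
converts scores to percentile ranks — rank/(n+1) × 100, mean rank for
ties, hence invariant under monotone transforms — and takes each
infant's max−min range across timepoints; composite-vs-single-variable
contrasts are paired t-tests, with zero-variance difference vectors
flagged as degenerate rather than tested. ASQ outcomes are longitudinal
mixed models (random intercept per participant, random slope on the
assessment index) with age and sex covariates and the five composites
as predictors; singular fits fall back to random-intercept-only, then
to OLS, each with a warning. Outliers are flagged per variable within
timepoint by Tukey fences (1.5 × IQR); fits are reported with and
without them.

## The synthetic cohort

The generator's defaults are the study conditions: 150 infants × 3
assessments (exact ages uniform in 2.43–3.39, 5.42–6.28 and 11.47–12.26
months), recording lengths ~N(11.13, 1.17)/(10.60, 1.91)/(10.55, 1.93)
nights clipped to 7–14 (cohort mean ≈ 10.76 days). Five latent factors
per infant-timepoint are drawn from a correlation matrix whose four
largest entries are the reported inter-composite correlations
(activity–day 0.50, timing–variability 0.48, day–night −0.26,
night–timing −0.25); the remaining six pairs are small values of
matching sign structure chosen once (positive-definiteness asserted).
Each factor splits into a stable participant component and an occasion
component (persistence 0.60 timing, 0.50 night, 0.30 others), giving
cross-age rank stability of realistic size. Female infants get a −0.29
SD shift on the activity factor; small exact-age slopes (−0.15
activity, −0.21 day, −0.07 timing, −0.08 variability, +0.03 night per
month) act within each assessment window, while the age trend *between*
assessments is carried by the per-timepoint calibration targets
themselves (bedtimes, wake-bout rates, nap counts per printed 3/6/12-month
descriptives) — injecting it twice would double-count.

Realization is bout-level, not a per-minute Markov chain, because the
measured variables are run-length statistics: nights get
bedtime/get-up anchors (timing factor shifts both; night factor
lengthens the window), a gamma settling latency, Poisson wake bouts with
log-normal lengths (rate and length scale log-linearly with the
activity factor, which also scales the night-to-night *dispersion* of
the rate — fragmented sleepers are also irregular in their
fragmentation); days get log-normal naps whose number and length follow
the day factor; the variability factor scales all night-to-night jitter
log-linearly (scale 0.70). Two deliberately modelled measurement
features keep the between-variable correlation structure five-factor
dominated, as the cohort design intends: parents report bed/get-up
times on a 5-min grid with recall noise proportional to their own
household irregularity, and about half of nights contain a brief
resettling bout minutes after first sleep, so the consolidated
(≥ 10-min) onset carries night-to-night variance of its own rather than
duplicating the bedtime series. Without these, near-duplicate
measurement channels (reported bedtime vs derived onset; their
cross-day SDs) form spurious doublet components that no real five-factor
summary would show. One side effect: the consolidated onset lands later
than first sleep on resettle nights, so the generator's mean latency
runs above the printed 8–11 min (latency is not among the retained
variables).

Activity counts are gamma draws conditional on state (wake ≈ shape 3,
mean 420–520; sleep = sparse bursts at the printed percent-active rates);
diaries are 15-min majority down-samples with 5% interval noise; 5% of
reported anchors are blank (exercising the first/last-reported-sleep
fallback). Missingness injection adds removal episodes (~0.25/day,
log-normal ~45 min, 10% not covered by the diary), 2% sick days, 2%
assessment dropout and rare metadata exclusion flags. All draws descend
from one master seed through per-participant `SeedSequence` spawns, so
cohorts are byte-identical given a seed.

What the generator does **not** emulate: circadian or ultradian
physiology beyond bout statistics, seasonal/light effects, device
calibration error, developmental change within a recording, or
correlated diary failure modes (a tired parent mis-reporting whole
nights). Passing recovery tests on this cohort therefore shows the
pipeline's *internal* consistency — that the analysis recovers the
structure the data actually contain — not that real infant data contain
that structure. Note one consequence of the multiplicative design: a
zero variability factor means *typical*, not absent, night-to-night
jitter (no infant repeats its schedule exactly), so the tests assert
the monotone property — a lower factor yields smaller realized
day-to-day SDs — rather than a degenerate zero-jitter case.

## Problem sizes and reproducibility

Tests and the acceptance script run the full cohort at its native size
(150 × 3, ~7 M minutes) once, with m = 3 imputations × 5 iterations for
the desk-scale analyses; the 20-cohort robustness check of the daytime
sleep → development association scores composites on the generator's
noiseless (truth-level) assessment matrices, which skips the scoring
and screening stages whose behaviour is already covered by the single
full run. The acceptance script holds the cohort at the package's
default configuration (including its default master seed) — these are
the study conditions — while the `--seed` argument drives the
analysis-side randomness (imputation chains, parallel-analysis
surrogates).

## Known limitations

* The Sadeh-style coefficients and smoothing lengths are package
  defaults, not the published infant-validated set; validation against
  polysomnography is out of scope.
* The diary-fit criterion (0.80 agreement) is a stand-in for an
  unpublished appendix rule.
* Imputation approximates the two-level scheme with single-level PMM
  plus covariates; with the cohort's low missingness (< 25% per
  variable) the difference is second-order, but clustered missingness
  would be handled less faithfully.
* Clock means are linear, not circular — adequate while all bedtimes
  fall in one evening band, wrong for free-running schedules.
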