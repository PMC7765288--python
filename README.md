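# infantsleep

Actigraphy-based phenotyping of infant sleep: from ankle-worn
accelerometer counts and 24-h parent diaries to 48 standard sleep
variables, five PCA-derived **sleep composites**, and their stability and
developmental-outcome analyses — plus a fully synthetic longitudinal
cohort generator so every stage is testable without any recordings.

## Who this is for

Infant sleep is usually quantified by combining a worn movement sensor
with a parent-kept 24-h diary. The field computes dozens of partially
overlapping variables (total sleep time, WASO, sleep efficiency, nap
counts, regularity indices, day-to-day variabilities, ...), which makes
variable selection arbitrary and multiple testing rampant. A
data-driven reduction pools all variables across participants and
assessment ages and extracts a small number of oblique principal
components — the sleep composites **Sleep Activity**, **Sleep Timing**,
**Sleep Night**, **Sleep Day** and **Sleep Variability** — each scored as
the unweighted mean of its variables' signed z-scores.

## The pipeline

1. **Ingest** (`infantsleep.ingest`) — tri-axial acceleration → per-minute
   activity counts (3–11 Hz band-pass, 15-s bins, axes fused by sum of
   squares), non-wear detection, diary fusion.
2. **Scoring** (`infantsleep.scoring`) — a Sadeh-style windowed linear
   classifier (configurable coefficients), a high/low-activity
   refinement at `mean(activity) × 0.72`, and run-length smoothing rules.
3. **Screening** (`infantsleep.screening`) — per-day, per-family validity:
   removal > 1 h kills partial-day variables, > 3 h entire-day, > 5 min
   movement-count; a removal inside a 30-min window on the reported
   on-/offset kills clock-time variables; sick days kill everything;
   days with poor diary agreement (< 0.80) are dropped.
4. **Variables** (`infantsleep.variables`) — the 48-slot registry: per-day
   calculators for night, daytime, and fixed-clock-window variables,
   Sleep Regularity Indices across consecutive days, and cross-day
   variability slots (sample SD over ≥ 5 valid days). Assessments need
   ≥ 3 valid days.
5. **Composites** (`infantsleep.composites`) — multiple imputation
   (chained equations, predictive mean matching), Horn's parallel
   analysis for the component count, PCA with promax rotation, pruning
   at |loading| < 0.512, assignment, scoring, Rubin pooling.
6. **Cohort statistics** (`infantsleep.stats`) — age/sex linear models,
   Spearman inter-correlations and cross-age stability (Bonferroni
   0.05/15 = 0.0033), within-subject percentile stability, paired
   stability contrasts, and longitudinal mixed models against ASQ
   developmental scores.
7. **Synthetic cohort** (`infantsleep.synth`) — five correlated latent
   factors per infant-timepoint drive a bout-level generator of minute
   states, counts, diaries, missingness and ASQ scores, with full ground
   truth retained.

## Worked example

```bash
python examples/03_composites.py
```

prints (60 synthetic infants, seed 42):

```
parallel analysis suggests 5 components (top eigenvalues [13.26  5.86  3.85  3.03  2.33  1.43])
Sleep Activity     <- 9 variables
Sleep Variability  <- 8 variables
Sleep Day          <- 7 variables
Sleep Timing       <- 5 variables
Sleep Night        <- 3 variables

per-infant composite scores (head):
                       Sleep Activity  Sleep Variability  Sleep Timing  Sleep Night  Sleep Day
participant timepoint
0           3                    0.41              -1.04         -0.51         0.43       0.18
1           3                    1.58               0.21          0.06         0.18       1.36
2           3                   -0.27              -0.28          1.69        -0.70       0.11
```

Five eigenvalues clear the random-data benchmark, so five composites are
retained; each variable joins the component it loads on most strongly,
and an infant's score is the mean of its variables' z-scores (sign-aligned
so that, e.g., higher Sleep Activity = more nocturnal movement and
waking). `examples/04_stability_and_development.py` continues with the
stability and ASQ analyses.

A thin CLI mirrors the stages
(`infantsleep synth|ingest|score|composites`); the Python API is the
primary surface.

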