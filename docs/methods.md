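# Methods

This note documents the models, rules and numerical choices implemented in
`thermocycle`, the assumptions behind the synthetic-cohort generator, and
what the package's tests do and do not establish about real data.

## Data model

A menstrual cycle starts on the first day of bleeding (cycle day 1; all day
indices are 1-based and intervals inclusive). Each cycle carries a daily
wrist-temperature series, a daily BBT series (missing days as NaN,
physiologic band 30–42 °C), and a daily LH test record with at most one
positive day (testing stops at the first positive).

The LH record is the reference standard: ovulation day = positive day + 1;
only-negative cycles are anovulatory; a cycle with no tests has no reference
standard and is excluded. Quality control also drops cycles with ≥ 30 % of
days missing in either temperature series (the threshold is inclusive and
configurable).

Phases: follicular = days 1…ov, luteal = ov+1…L, so luteal length = L − ov.
The three curve-comparison windows are menstrual [1, min(5, L)],
preovulatory [max(1, ov−10), ov], postovulatory [ov+1, min(ov+10, L)];
menstrual and preovulatory windows may overlap for early ovulation and are
analysed independently.

## Nightly reduction

A night is one contiguous 10-s stream; sensor dropouts longer than 10 min
split a recording and only the longest segment is kept. Nights shorter than
4 h (measured as n_samples × interval on the pre-trim stream) yield a
missing daily value. The first 90 and last 30 minutes are removed (540 +
180 samples at 10-s sampling), the remainder is smoothed with a LOWESS
smoother — local linear fits, tricube weights, single pass, window equal to
30 minutes of recording expressed as a fraction of the stream — and the
99th percentile of the smoothed stream (linear interpolation between order
statistics) is the daily value. Percentiles 10/50/90 reproduce the other
candidate reductions.

Numerical notes: the smoother evaluates on a grid with spacing 1 % of the
stream and interpolates linearly between fit points (`lowess_delta_frac`,
set to 0 for exact per-point fits); the reduction is equivariant under
constant shifts and monotone in the percentile, and the 99th percentile of
smoothed noise adds a small, nearly night-constant positive offset
(≈ +0.03 °C at AR(1) noise SD 0.05), which cancels in shift detection
because the rule compares days to days.

## Temperature-shift rule

Day d starts a shift iff (a) days d, d+1, d+2 are non-missing, (b) at least
5 of the 6 days before d are non-missing, (c) every run value is
≥ max(present baseline) + 0.2 °C, and (d) d lies in the last 14 days of the
cycle with the full run inside the cycle (L−13 ≤ d ≤ L−2). Choices worth
stating: the 0.2 °C threshold is inclusive and compared at full precision;
the three run days must all be non-missing (the five-of-six allowance is
worded for the baseline only); the baseline may extend before the 14-day
window; and every qualifying start day is counted, so overlapping
detections give multi-shift cycles. All of these are configurable in
`ShiftRuleConfig`.

## Diagnostic accuracy

Test positive = ≥ 1 shift; condition positive = ovulatory by LH.
Sensitivity, specificity, PPV and NPV are plain ratios with zero-denominator
measures reported as absent, never 0/0. Default CIs are exact
Clopper–Pearson with a Wilson option — the naive binomial interval is the
primary output, and clustering of cycles within women is addressed by a
percentile cluster bootstrap (participants resampled with replacement, all
their cycles retained; replicates with empty denominators skipped and
counted) offered as a sensitivity analysis. Paired modality comparisons use
the exact two-sided McNemar test on discordant pairs within the relevant
stratum (ovulatory cycles for sensitivity, anovulatory for specificity):
p = min(1, 2·P[Bin(b+c, ½) ≤ min(b, c)]), and p = 1 with no discordant
pairs. Presentation rounding is 2 decimals for proportions and 1 decimal
for percentages.

## Repeated-measures correlation

r_rm is computed from the ANCOVA definition rather than through a wrapper:
center x and y within participant, fit the common slope b = Σx~c~y~c~/Σx~c~²,
and set r_rm = sign(b)·√(SS_x/(SS_x+SS_e)) with SS_x = b²Σx~c~²,
df = N − k − 1. The p-value comes from F(1, df) = r²/(1−r²)·df and the CI
from Fisher's z with standard error 1/√(df−1) (the reference
implementation's analytic option). Participants with fewer than two
observations are dropped with a warning; a single remaining participant
degenerates exactly to the Pearson correlation (df = N−2), allowed with a
warning. The identity r_rm² = partial η² of the covariate is covered by a
test against an explicit least-squares decomposition.

## Daily curve estimation

Within each phase the fixed-effect structure is day-as-categorical, so each
coefficient is directly the estimated mean temperature of that
phase-relative day. The hierarchy (days within cycles within participants)
enters as a participant random intercept plus random slope on the numeric
day, and a cycle-within-participant random intercept (variance component).
Full random slopes at both levels are not identifiable at realistic cohort
sizes. Singular or non-finite fits fall back in order: random intercepts at
both levels → participant intercept only → raw day means with
normal-theory CIs; zero-variance data return exact means with zero-width
CIs. Daily differences between modality curves are elementwise on the
common day index. Cycle-level display curves use the same LOWESS smoother
with span 0.5 over the ≤ 11-day window (display only, never in the
statistics).

## Synthetic cohort generator

The generator's defaults are the study conditions: 57 participants; 1–6
cycles per woman with probabilities (2, 5, 23, 17, 9, 1)/57 (mean 3.5);
12 % anovulatory cycles; cycle length ~ N(29.5, 4.5²) truncated to [21, 60]
and rounded; luteal length ~ N(12.2, 1.9²) truncated to [3, min(20, L−2)];
wrist follicular plateau ~ N(35.78, 0.30²) between participants with luteal
elevation ~ N(0.29, 0.21²) between cycles; BBT level ~ N(36.25, 0.15²) with
elevation ~ N(0.26, 0.10²); iid day-to-day noise SD 0.10 °C (wrist) and
0.15 °C (BBT); 10 % per-day missingness per modality. Anovulatory cycles
have zero elevation and no LH positive.

The luteal elevation switches on as a logistic ramp centred at the
ovulation day with scale 0.5 days, i.e. the 10–90 % transition spans about
two days. Nightly streams rise from plateau − 1.5 °C over the first 90 min
(logistic shape rescaled to reach the plateau exactly), hold the plateau
with stationary AR(1) noise (SD 0.05 °C, lag-1 correlation 0.95 at 10-s
sampling — an assumption; no published within-night noise statistics
exist), and decline over the final 20 min; the standard trim therefore
isolates the plateau. Sleep duration ~ N(7.5, 1²) h truncated to [4, 10].

LH testing starts at round(mean cycle length − 17) = day 12 and runs daily
until the first positive (the day before ovulation) or the end of the
cycle. When ovulation is early enough that the surge precedes the schedule,
testing is moved up to the surge day so that the reference standard always
captures ovulatory cycles — emulating a study population in which
reference-missing cycles have already been excluded.

Randomness is hierarchical (independent substreams per participant, cycle
and night derived from the root seed), so identical seeds give
byte-identical cohorts and enlarging the cohort never changes existing
participants.

### What the generator does and does not emulate

It reproduces the nested cohort structure, the temperature levels and
between-phase contrasts, LH timing, nightly stream shape and missingness.
It does **not** couple the two modalities beyond sharing ovulation timing
(participant effects and noise are independent across modalities, so
simulated repeated-measures correlations between wrist and BBT means sit
near zero), does not model a continuing postovulatory drift beyond the
onset ramp, day-to-day noise autocorrelation, sensor drift, or behavioural
confounders (alcohol, illness, wake-time variation). Passing tests
therefore validate the pipeline's correctness and internal consistency,
not field performance on real cohorts.

### Detection rates under the default conditions

With the defaults the 3-over-6 rule is conservative: detection of a shift
requires three consecutive daily noise draws to clear the maximum of the
six preceding draws minus (elevation − 0.2 °C). At elevation 0.29 °C and
day-noise SD 0.10 °C that margin is −0.09 °C while the expected max-of-6
minus min-of-3 noise gap is ≈ 0.21 °C, so per-cycle detection probabilities
are small: measured wrist biphasic rates are ≈ 0.03 at a fixed 0.29 °C
elevation (zero at zero elevation), and on full-default cohorts wrist
sensitivity ≈ 0.14 versus BBT ≈ 0.05 — reproducing the direction of the
wrist-over-BBT ordering, not the magnitudes, which in real data depend on
noise structure and rise shapes not recoverable from published summaries.

## Problem sizes

The test suite runs cohorts of up to ~500 cycles through the full
night-stream pipeline (~15 000 simulated nights) and the acceptance script
uses the study-scale 57-participant cohort; both complete in well under two
minutes on one CPU.

## Known limitations

- The LOWESS span, the smoothing-versus-percentile order, and the
  mixed-model fixed/random structure are reasoned choices where published
  descriptions are silent; all are exposed in configuration objects.
- The cluster bootstrap is percentile-based; BCa corrections are not
  implemented.
- Bleeding-date discrepancies between devices, calendar/time-zone handling,
  and non-temperature wearable channels are out of scope.
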