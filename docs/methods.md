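# Methods

This note documents the models and procedures somnalign implements, the
defaults it ships, and the choices made where the design was genuinely
open.

## Nightly sleep derivation

All derivation runs on instants standardized to Europe/Helsinki;
conversion never moves an instant on the absolute timeline, only its
wall-clock rendering (winter +02:00, summer +03:00). Days are the local
half-open windows [15:00 of day D, 15:00 of day D+1), chosen so that a
whole night of sleep falls inside one window regardless of whether it
starts before or after midnight. Onset/offset arithmetic everywhere uses
*window-relative minutes* (minutes since the 15:00 window start), which
makes averages and deviations across midnight well defined; clock
strings are produced only for display.

Per modality:

* **Actigraph / bed sensor.** A sleep-marked sample (a `REST-S` 30-s
  epoch, a status-`1` second) covers the half-open interval
  [t, t + step). Maximal runs of marked samples form episodes; two runs
  whose separating gap is at most 5 minutes (inclusive — "up to 5
  minutes") are merged, the gap counting toward the episode's span. The
  same rule is applied at both sampling rates; the gap threshold is a
  parameter (`gap_threshold_min`).
* **Smartphone.** Screen events drive a two-state machine: `lock`/`off`
  enter inactivity, `unlock`/`on` end it. Repeated same-direction events
  are ignored (the first lock of a lock,lock,unlock run opens the
  interval); a log starting mid-state opens at its first observed
  transition, never by extrapolation. Maximal inactive intervals are the
  sleep candidates. Two contradictory events at the same instant have no
  well-defined interval semantics; the implementation processes events
  in row order, which is pinned by tests.
* **EMA.** The morning category maps to its midpoint in hours
  ("6-7 hours" → 6.5). The open-ended bins take half an hour beyond
  their bound ("under 5 hours" → 4.5, "over 10 hours" → 10.5),
  consistent with the one-hour width of the interior bins; no interior
  evidence constrains these two values, so they are parameters of the
  mapping table. A response dated D describes the night of study day
  D − 1.

An episode belongs to the window containing its *onset* (a single
unambiguous assignment; nocturnal episodes never straddle 15:00 in
practice). Within each participant-window the longest episode is the
night's main sleep, ties broken by earliest onset for determinism.
Selection happens *before* the plausibility filter: a main episode whose
TST falls outside 3–13 h (bounds inclusive) yields no record for that
day rather than promoting the second-longest candidate — the filter
excludes implausible nights, it does not re-select.

Outlier handling operates per modality on the participant-day table: for
each of the onset and offset columns (window-relative minutes), the k=2
rows with the largest absolute deviation from the column mean are
flagged, and the union of flagged rows is removed (a row flagged by both
columns is removed once; ties break by first occurrence). Tables with
≤ k rows are left untouched with a warning. Operating on rows rather
than participant means is a choice; k is configurable.

## Agreement statistics

Participants are aggregated by averaging their surviving days per
modality; all pairwise statistics are computed at the participant level
(a day-level variant exists for diagnostics). Only pairwise-complete
participants enter a comparison, so n differs across pairs. The pair
label "A vs B" always means A − B.

Bland-Altman: mean bias d̄, sample SD (n−1), 95% limits of agreement
d̄ ± 1.96·SD (the conventional normal quantile, not a t-quantile), and a
t-based CI for the bias (t quantile, df = n−1). Zero-variance
differences collapse the LoA onto the bias and flag the result as
degenerate (t undefined). Paired t is the standard one-sample test on
the differences, two-sided.

Pearson r carries a Fisher-z 95% CI, tanh(atanh r ± z₀.₉₇₅/√(n−3)), and
an exact-t p-value. The Fisher-z construction keeps the CI inside
[−1, 1]; published tables in this literature sometimes print
regression-slope CIs that exceed 1, which this package deliberately does
not imitate. Shapiro-Wilk normality is reported alongside r but never
blocks the Pearson analysis. Magnitudes are labelled by the Mukaka
bands with boundaries taking the higher band (0.70 → high).

## Mixed models

For each metric (onset, offset, TST) and modality pair, the day-level
absolute difference in **hours** is the outcome of a random-intercept
model fitted by REML (statsmodels MixedLM):

    abs_diff ~ age + sex + MEQ + daylight + group,  (1 | participant)

with male and control as reference levels, Wald CIs and p-values. Hours
is the only scale on which coefficient magnitudes around ±1 for a binary
predictor are plausible. Nine models (3 metrics × 3 sensor pairs) are
fitted with no multiple-testing correction.

Derived summaries: ICC = τ00/(τ00 + σ²); Nakagawa marginal R² =
var(Xβ̂)/(var(Xβ̂) + τ00 + σ²) and conditional R² adds τ00 to the
numerator (variance of the fixed-effect predictions with ddof = 1). The
fitted ICC is exactly the arithmetic identity on the fitted components.
A boundary fit (τ00 → 0) is returned with a `singular` flag rather than
raised. The implementation is cross-checked against an lme4 REML fit on
identical data in the test suite.

**Daylight scale.** Daylight enters per *hour* by default. A per-minute
coefficient of the magnitudes typically reported (≈ −0.1) would imply a
multi-hour alignment change across a Finnish season per minute of
daylight, which is physically implausible; both scalings are available
(`daylight_scale`), and slope/p invariance under rescaling is tested.

**Day length.** Sunrise-to-sunset minutes from a NOAA-style solar
position chain (Julian century → apparent solar longitude → declination
→ sunrise hour angle at zenith 90.833°), longitude nudging the
evaluation to local solar noon. Accuracy is well under a minute at
temperate latitudes (tested against an independent Astronomical Almanac
ephemeris); polar day/night clamp to 1440/0. Default coordinates are
Helsinki (60.17 N, 24.94 E).

## Synthetic cohort generator

The generator *is* the study conditions for every end-to-end test. Its
defaults (shipped in `defaults.yaml`) describe a 14-day active phase
starting 2019-03-01 in Helsinki with 50 controls and 119 patients
(78 MDD, 21 BD, 20 BPD).

* **Timing.** Participant mean onset/offset are Gaussian around group
  means (controls ≈ 23:55/07:35; patients ≈ 00:30–00:35/08:30–08:40,
  window-relative), with larger between-participant and night-to-night
  SDs for patients (controls 40–65 min; patients 60–100 min). Nightly
  draws are truncated at the window edges and to 3–13 h duration.
* **Device error.** Each sensor observes the truth through a fixed
  systematic shift (bed = reference 0/0; actigraph +2 min onset /
  +30 min offset — wake misclassified as sleep at the end of the night;
  smartphone +6 / −38 min — the first phone use precedes the true wake
  report), plus a persistent per-participant bias (SD 40–60 min) and
  per-night jitter (SD 25–40 min). The persistent component is what
  gives Bland-Altman SDs their realistic 60–110 min magnitude at the
  participant level.
* **EMA.** Perceived TST = true TST − 20 min + N(0, 45 min), then
  binned; the small systematic under-report mirrors self-report
  behavior.
* **Missingness.** Bernoulli per participant-night-modality (actigraph
  0.15, bed 0.12, smartphone 0.05, EMA 0.20) — attrition magnitudes,
  not a mechanism model.
* **Season.** True offsets shift by −3 min per hour of daylight beyond
  12 h (longer days → earlier waking), with day length computed for the
  study site.
* **Rendering.** Actigraph renders the full window at 30 s with
  occasional `REST` among waking `ACTIVE` epochs and an optional
  mid-sleep `ACTIVE` interruption (default 3 min at p = 0.1, which the
  5-min merge must absorb). The bed stream renders at 1 Hz with a 30-min
  non-sleep margin around sleep (status 0/2, optional status-3 burst);
  status-0 time away from the bed carries no information for
  derivation, so it is not materialized for the whole window. Screen
  usage is a renewal process of unlock–lock bouts (gaps uniform
  10–70 min, bout length exponential mean 6 min) with a final pre-sleep
  check locking exactly at the biased onset and a morning unlock at the
  biased offset; bounded daytime gaps guarantee the night is the longest
  inactivity interval.

What the generator does **not** emulate: within-night wake architecture
(real patients fragment sleep in structured ways; interruptions here are
parameterized, not calibrated), naps, co-sleeping artifacts in the bed
signal, correlated missingness (device abandonment), and any raw-signal
physiology — the proprietary label algorithms of real devices are out of
scope, the generator produces their *outputs*. Passing tests therefore
demonstrate that the pipeline and estimators are correct under the
stated error model, not that any particular real device is unbiased.

## Determinism and numerics

A cohort seed fixes everything: generation and rendering use separate
children of the seed, drawn in a fixed participant/night order, so equal
configs give byte-identical streams. Ingest validates values against
closed vocabularies (hard error naming the offending row), keeps the
first of duplicate timestamps with a warning, and only ever removes —
never fabricates — instants. Zero-length or inverted intervals from
malformed logs are dropped with a warning. Display rounding is half-up
to 2 decimals; CSVs keep full precision.

## Problem sizes in validation

The validation suite uses scaled designs chosen to make Monte-Carlo
error small relative to each check's tolerance: oracle equivalence on
1000 random streams; Bland-Altman bias recovery on 60 participants × 14
nights (tolerance 3·SD/√n); mixed-model CI coverage on 100 replicates of
150 × 14 tables (binomial band around 95%); type-I calibration on 1000
paired t replicates at n = 30 (±3σ band around 5%); LoA coverage on
2000 Gaussian differences. Larger cohorts change none of the logic, only
the sampling error.
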