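# Default synthetic-cohort parameters.
#
# Group sleep-timing parameters are window-relative minutes (minutes after
# the 15:00 window start; 535 = 23:55 local).  Magnitudes mirror the mean
# (SD) onset/offset/TST structure reported for controls vs patients in the
# study population the generator emulates: patients sleep later and are
# substantially more variable night to night and between individuals.
groups:
  control:
    onset_mean_min: 535.0        # ~23:55
    onset_between_sd_min: 55.0   # between-participant SD of mean onset
    onset_within_sd_min: 40.0    # night-to-night SD
    offset_mean_min: 995.0       # ~07:35
    offset_between_sd_min: 65.0
    offset_within_sd_min: 45.0
  MDD:
    onset_mean_min: 570.0        # ~00:30
    onset_between_sd_min: 80.0
    onset_within_sd_min: 60.0
    offset_mean_min: 1050.0      # ~08:30
    offset_between_sd_min: 95.0
    offset_within_sd_min: 70.0
  BD:
    onset_mean_min: 575.0
    onset_between_sd_min: 85.0
    onset_within_sd_min: 65.0
    offset_mean_min: 1060.0
    offset_between_sd_min: 100.0
    offset_within_sd_min: 75.0
  BPD:
    onset_mean_min: 575.0
    onset_between_sd_min: 85.0
    onset_within_sd_min: 65.0
    offset_mean_min: 1055.0
    offset_between_sd_min: 100.0
    offset_within_sd_min: 75.0

demographics:
  age_mean: 35.1
  age_sd: 12.8
  age_range: [18, 75]
  female_prop: 0.74
  meq_mean: 39.2
  meq_sd: 5.2

# Device-specific systematic biases relative to the true sleep interval
# (positive = device reports later), a persistent per-participant bias
# component, and per-night jitter.  The bed sensor is the reference; the
# actigraph tends to extend sleep at the end (wake misclassified as sleep)
# and the smartphone to cut it short (first phone use precedes final wake).
devices:
  actigraph:
    onset_bias_min: 2.0
    offset_bias_min: 30.0
    participant_bias_sd_min: 40.0
    jitter_sd_min: 25.0
    missing_prob: 0.15
  bed:
    onset_bias_min: 0.0
    offset_bias_min: 0.0
    participant_bias_sd_min: 40.0
    jitter_sd_min: 25.0
    missing_prob: 0.12
  smartphone:
    onset_bias_min: 6.0
    offset_bias_min: -38.0
    participant_bias_sd_min: 60.0
    jitter_sd_min: 40.0
    missing_prob: 0.05

ema:
  bias_min: -20.0              # slight self-report underestimate of TST
  misperception_sd_min: 45.0
  missing_prob: 0.20

seasonal:
  # minutes of true-offset shift per hour of daylight beyond 12 h
  # (longer days -> earlier waking)
  offset_min_per_daylight_hour: -3.0

render:
  actigraph:
    rest_prob: 0.05            # P(REST) per awake epoch
    interruption_prob: 0.10    # P(one mid-sleep ACTIVE interruption)
    interruption_min: 3.0      # interruption length (merged downstream)
  bed:
    awake_in_bed_prob: 0.15    # P(status 2) per non-sleep sample
    overload_prob: 0.10        # P(one mid-sleep status-3 burst)
    overload_min: 3.0
    margin_min: 30.0           # non-sleep context rendered around sleep
  screen:
    day_usage: true            # render daytime usage bouts at all
    gap_range_min: [10, 70]    # uniform gap between daytime usage bouts
    bout_min_mean: 6.0         # mean bout length, exponential (clipped 0.5-20)
    prebout_min: 5.0           # phone check ending at sleep onset
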