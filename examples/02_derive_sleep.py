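"""Derive nightly sleep records from rendered raw streams.

One synthetic night is rendered into all four modalities, then the full
derivation (5-min gap merge, 3 PM windows, longest episode, 3-13 h
filter) turns the streams back into onset/offset/TST rows.
"""

import numpy as np

from somnalign import build_daily_records, load_default_params
from somnalign.synthetic import CohortConfig, simulate_cohort

config = CohortConfig(n_controls=1, n_patients_by_group={}, n_days=3, seed=4)
params = load_default_params()
for dev in params["devices"].values():
    dev["missing_prob"] = 0.0
params["ema"]["missing_prob"] = 0.0

sim = simulate_cohort(config, params)
print(f"rendered rows: actigraph={len(sim.actigraph)}, bed={len(sim.bed)}, "
      f"screen={len(sim.screen)}, ema={len(sim.ema)}\n")

daily, removed, attrition = build_daily_records(
    sim.actigraph, sim.bed, sim.screen, sim.ema, outlier_k=0
)
for _, r in daily.iterrows():
    onset = "—" if r["modality"] == "ema" else f"{r['onset']:%H:%M}"
    offset = "—" if r["modality"] == "ema" else f"{r['offset']:%H:%M}"
    print(f"{r['study_day']}  {r['modality']:>10}: onset {onset:>5}  offset {offset:>5}"
          f"  TST {r['tst_min'] / 60:.1f} h")

truth = sim.truths[0]
print(f"\nground truth night 1: {truth.true_onset:%H:%M} -> {truth.true_offset:%H:%M}")
# Sensor rows differ from the truth by each device's injected bias/jitter;
# the EMA row is the category midpoint of the (noisy) perceived duration.
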