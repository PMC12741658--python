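"""Synthetic multimodal sleep cohort with known ground truth.

The generator emulates the study design the pipeline targets: a cohort of
healthy controls and patients (MDD, BD, BPD) observed for a 2-week active
phase in Helsinki, each participant-night producing

* a 30-second actigraph epoch-label stream (ACTIVE/REST/REST-S),
* a 1 Hz bed-sensor status stream (1 = asleep; 0/2/3 non-sleep),
* a smartphone screen-event log (on/off/lock/unlock), and
* a morning EMA report of last night's sleep as a duration category,

all derived from a latent true sleep interval.  Night-level timing is
Gaussian around participant means (truncated at the 3 PM window edges);
patients sleep later with larger night-to-night and between-participant
spread.  Each sensor observes the truth through a systematic device bias,
a persistent per-participant bias and per-night jitter, with Bernoulli
per-night missingness — so every downstream estimate (Bland-Altman bias,
mixed-model coefficients) has a known target.

Defaults live in ``defaults.yaml`` next to this module and are fully
overridable.
"""

from __future__ import annotations

import datetime as dt
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .derive import window_start
from .ingest import (
    BedStatusStream,
    EmaResponseTable,
    EpochLabelStream,
    ScreenEventLog,
)
from .solar import day_length

__all__ = [
    "CohortConfig",
    "ParticipantProfile",
    "GroundTruthNight",
    "SimulatedCohort",
    "load_default_params",
    "generate_cohort",
    "render_actigraph",
    "render_bed",
    "render_screen",
    "render_ema",
    "simulate_cohort",
    "bin_tst_category",
    "profiles_to_demographics",
]

MODALITIES = ("actigraph", "bed", "smartphone", "ema")
_SENSORS = ("actigraph", "bed", "smartphone")


def load_default_params() -> dict:
    """The shipped default parameter set (deep copy; mutate freely)."""
    text = importlib.resources.files("somnalign").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: sizes, calendar placement, site, seed.

    Defaults mirror the target study: 50 controls and 119 patients
    (78 MDD, 21 BD, 20 BPD) observed for a 14-day active phase at
    Helsinki's coordinates.
    """

    n_controls: int = 50
    n_patients_by_group: dict = field(
        default_factory=lambda: {"MDD": 78, "BD": 21, "BPD": 20}
    )
    study_start_date: dt.date = dt.date(2019, 3, 1)
    n_days: int = 14
    latitude: float = 60.17
    longitude: float = 24.94
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 0 or any(v < 0 for v in self.n_patients_by_group.values()):
            raise ValueError("participant counts must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent per-participant parameters (the demographics row + timing)."""

    participant: str
    group: str
    age: float
    sex: str
    meq: float
    mean_onset_rel: float  # window-relative minutes
    mean_offset_rel: float
    onset_sd: float  # night-to-night SDs
    offset_sd: float


@dataclass(frozen=True)
class GroundTruthNight:
    """One participant-night of latent truth plus realized device effects."""

    participant: str
    date: dt.date  # study day (3 PM window start date)
    true_onset: pd.Timestamp
    true_offset: pd.Timestamp
    device_bias: dict  # modality -> (onset shift min, offset shift min)
    missing: dict  # modality -> bool

    def __post_init__(self):
        if self.true_offset <= self.true_onset:
            raise ValueError("true_offset must follow true_onset")

    @property
    def true_tst_min(self) -> float:
        return (self.true_offset - self.true_onset).total_seconds() / 60.0


@dataclass
class SimulatedCohort:
    """Everything one simulation run produces."""

    profiles: list
    truths: list
    actigraph: EpochLabelStream
    bed: BedStatusStream
    screen: ScreenEventLog
    ema: EmaResponseTable
    demographics: pd.DataFrame


def _ts(day: dt.date, rel_min: float) -> pd.Timestamp:
    """Window-relative minutes -> absolute instant (rounded to seconds)."""
    return window_start(day) + pd.to_timedelta(int(round(rel_min * 60)), unit="s")


def generate_cohort(config: CohortConfig, params: dict | None = None):
    """Draw participant profiles and per-night ground truth.

    Deterministic given ``config.seed``.  Returns ``(profiles, truths)``;
    zero participants yield empty lists.
    """
    p = params or load_default_params()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    demo = p["demographics"]
    seas = p["seasonal"]["offset_min_per_daylight_hour"]

    memberships = [("control", config.n_controls)] + [
        (g, config.n_patients_by_group.get(g, 0)) for g in ("MDD", "BD", "BPD")
    ]
    profiles: list[ParticipantProfile] = []
    truths: list[GroundTruthNight] = []
    idx = 0
    daylight_cache: dict[dt.date, float] = {}
    for group, n in memberships:
        gp = p["groups"][group]
        for _ in range(n):
            idx += 1
            pid = f"P{idx:03d}"
            age = float(np.clip(rng.normal(demo["age_mean"], demo["age_sd"]), *demo["age_range"]))
            sex = "female" if rng.random() < demo["female_prop"] else "male"
            meq = float(np.clip(rng.normal(demo["meq_mean"], demo["meq_sd"]), 16, 86))
            mean_onset = float(
                np.clip(rng.normal(gp["onset_mean_min"], gp["onset_between_sd_min"]), 60, 1250)
            )
            mean_offset = float(
                np.clip(
                    rng.normal(gp["offset_mean_min"], gp["offset_between_sd_min"]),
                    mean_onset + 180,
                    min(mean_onset + 780, 1430),
                )
            )
            profiles.append(
                ParticipantProfile(
                    pid,
                    group,
                    age,
                    sex,
                    meq,
                    mean_onset,
                    mean_offset,
                    gp["onset_within_sd_min"],
                    gp["offset_within_sd_min"],
                )
            )
            # persistent per-participant device bias components
            pbias = {
                m: (
                    rng.normal(0, p["devices"][m]["participant_bias_sd_min"]),
                    rng.normal(0, p["devices"][m]["participant_bias_sd_min"]),
                )
                for m in _SENSORS
            }
            for d in range(config.n_days):
                day = config.study_start_date + dt.timedelta(days=d)
                if day not in daylight_cache:
                    daylight_cache[day] = day_length(day, config.latitude, config.longitude)
                onset = mean_onset + rng.normal(0, gp["onset_within_sd_min"])
                offset = (
                    mean_offset
                    + rng.normal(0, gp["offset_within_sd_min"])
                    + seas * (daylight_cache[day] / 60.0 - 12.0)
                )
                onset = float(np.clip(onset, 0.0, 1250.0))
                offset = float(np.clip(offset, onset + 180.0, min(onset + 780.0, 1439.0)))
                bias = {
                    m: (
                        p["devices"][m]["onset_bias_min"]
                        + pbias[m][0]
                        + rng.normal(0, p["devices"][m]["jitter_sd_min"]),
                        p["devices"][m]["offset_bias_min"]
                        + pbias[m][1]
                        + rng.normal(0, p["devices"][m]["jitter_sd_min"]),
                    )
                    for m in _SENSORS
                }
                missing = {
                    m: bool(rng.random() < p["devices"][m]["missing_prob"]) for m in _SENSORS
                }
                missing["ema"] = bool(rng.random() < p["ema"]["missing_prob"])
                truths.append(
                    GroundTruthNight(pid, day, _ts(day, onset), _ts(day, offset), bias, missing)
                )
    return profiles, truths


def _biased_interval(truth: GroundTruthNight, modality: str):
    on_shift, off_shift = truth.device_bias.get(modality, (0.0, 0.0))
    onset = truth.true_onset + pd.to_timedelta(int(round(on_shift * 60)), unit="s")
    offset = truth.true_offset + pd.to_timedelta(int(round(off_shift * 60)), unit="s")
    w0, w1 = window_start(truth.date), window_start(truth.date + dt.timedelta(days=1))
    onset = max(onset, w0)
    offset = min(max(offset, onset + pd.Timedelta(seconds=60)), w1 - pd.Timedelta(seconds=1))
    return onset, offset


def render_actigraph(
    truth: GroundTruthNight, noise_params: dict | None = None, rng=None
) -> EpochLabelStream:
    """30-second epoch labels for one night's full 3 PM -> 3 PM window.

    REST-S covers the device-biased sleep interval (half-open on the
    grid); awake epochs are ACTIVE with occasional REST.  An optional
    mid-sleep ACTIVE interruption of configurable length exercises the
    downstream gap-merge rule.  A missing night yields an empty stream.
    """
    p = noise_params or load_default_params()["render"]["actigraph"]
    rng = np.random.default_rng(0) if rng is None else rng
    cols = ["participant", "timestamp", "label"]
    if truth.missing.get("actigraph", False):
        return EpochLabelStream(data=pd.DataFrame(columns=cols))
    w0 = window_start(truth.date)
    w1 = window_start(truth.date + dt.timedelta(days=1))
    grid = pd.date_range(w0, w1, freq="30s", inclusive="left")
    onset, offset = _biased_interval(truth, "actigraph")
    asleep = (grid >= onset) & (grid < offset)
    labels = np.where(
        asleep, "REST-S", np.where(rng.random(len(grid)) < p["rest_prob"], "REST", "ACTIVE")
    )
    n_sleep = int(asleep.sum())
    gap_epochs = int(round(p["interruption_min"] * 2))
    if rng.random() < p["interruption_prob"] and n_sleep > gap_epochs + 20:
        start = rng.integers(10, n_sleep - gap_epochs - 10)
        sleep_idx = np.flatnonzero(asleep)
        labels[sleep_idx[start : start + gap_epochs]] = "ACTIVE"
    df = pd.DataFrame({"participant": truth.participant, "timestamp": grid, "label": labels})
    return EpochLabelStream(data=df[cols])


def render_bed(truth: GroundTruthNight, noise_params: dict | None = None, rng=None) -> BedStatusStream:
    """1 Hz bed-sensor status for one night.

    Status 1 spans the biased sleep interval; a margin of non-sleep
    context (status 0, occasionally 2 = awake in bed) is rendered around
    it, with an optional short status-3 (signal overload) burst inside
    sleep.  A missing night yields an empty stream.
    """
    p = noise_params or load_default_params()["render"]["bed"]
    rng = np.random.default_rng(0) if rng is None else rng
    cols = ["participant", "timestamp", "status"]
    if truth.missing.get("bed", False):
        return BedStatusStream(data=pd.DataFrame(columns=cols))
    onset, offset = _biased_interval(truth, "bed")
    margin = pd.to_timedelta(p["margin_min"], unit="m")
    w0 = window_start(truth.date)
    w1 = window_start(truth.date + dt.timedelta(days=1))
    t0 = max(onset - margin, w0)
    t1 = min(offset + margin, w1)
    grid = pd.date_range(t0, t1, freq="1s", inclusive="left")
    asleep = (grid >= onset) & (grid < offset)
    status = np.where(asleep, 1, np.where(rng.random(len(grid)) < p["awake_in_bed_prob"], 2, 0))
    n_sleep = int(asleep.sum())
    burst = int(round(p["overload_min"] * 60))
    if rng.random() < p["overload_prob"] and n_sleep > burst + 600:
        start = rng.integers(300, n_sleep - burst - 300)
        sleep_idx = np.flatnonzero(asleep)
        status[sleep_idx[start : start + burst]] = 3
    df = pd.DataFrame({"participant": truth.participant, "timestamp": grid, "status": status})
    return BedStatusStream(data=df[cols])


def render_screen(truth: GroundTruthNight, usage_params: dict | None = None, rng=None) -> ScreenEventLog:
    """Screen lock/unlock events for one night's window.

    The final pre-sleep phone check locks exactly at the biased onset and
    the first morning use unlocks at the biased offset; daytime usage
    bouts (unlock ... lock pairs) are sprinkled through the awake part of
    the window.  A missing night yields an empty log.
    """
    p = usage_params or load_default_params()["render"]["screen"]
    rng = np.random.default_rng(0) if rng is None else rng
    cols = ["participant", "timestamp", "event"]
    if truth.missing.get("smartphone", False):
        return ScreenEventLog(data=pd.DataFrame(columns=cols))
    onset, offset = _biased_interval(truth, "smartphone")
    w0 = window_start(truth.date)
    w1 = window_start(truth.date + dt.timedelta(days=1))
    events: list[tuple[pd.Timestamp, str]] = []
    # pre-sleep check ending at onset; morning unlock at offset
    pre = pd.to_timedelta(p["prebout_min"], unit="m")
    events.append((max(onset - pre, w0), "unlock"))
    events.append((onset, "lock"))
    events.append((offset, "unlock"))
    events.append((offset + pd.to_timedelta(2, unit="m"), "lock"))
    # daytime usage bouts: a renewal process over each awake stretch, so
    # no daytime inactivity gap ever rivals the night in length
    if p.get("day_usage", True):
        gap_lo, gap_hi = p["gap_range_min"]
        awake: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        if (onset - pre) - w0 > pd.Timedelta(minutes=30):
            awake.append((w0, onset - pre - pd.Timedelta(minutes=1)))
        if w1 - offset > pd.Timedelta(minutes=30):
            awake.append((offset + pd.Timedelta(minutes=3), w1))
        for a, b in awake:
            t = a + pd.to_timedelta(float(rng.uniform(0, gap_lo)), unit="m")
            while t < b:
                dur = float(np.clip(rng.exponential(p["bout_min_mean"]), 0.5, 20.0))
                end = min(t + pd.to_timedelta(dur, unit="m"), b)
                if end > t:
                    events.append((t, "unlock"))
                    events.append((end, "lock"))
                t = end + pd.to_timedelta(float(rng.uniform(gap_lo, gap_hi)), unit="m")
    events.sort(key=lambda e: (e[0], e[1]))
    df = pd.DataFrame(
        {
            "participant": truth.participant,
            "timestamp": [t for t, _ in events],
            "event": [e for _, e in events],
        }
    )
    return ScreenEventLog(data=df[cols])


def bin_tst_category(hours: float) -> str:
    """Bin a perceived sleep duration into the seven EMA categories.

    Bins are left-closed: exactly 6 h falls in "6-7 hours".
    """
    if hours < 5:
        return "under 5 hours"
    if hours >= 10:
        return "over 10 hours"
    lo = int(hours)
    return f"{lo}-{lo + 1} hours"


def render_ema(
    truth: GroundTruthNight,
    misperception_sd: float = 45.0,
    rng=None,
    bias_min: float = 0.0,
):
    """Morning EMA response for one night, or ``None`` when missing.

    Perceived TST is the true TST plus a report bias and Gaussian
    misperception noise (minutes), then binned into the categorical
    answer.  The response is dated the morning after the study day.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    noise = float(rng.normal(0.0, misperception_sd)) if misperception_sd > 0 else 0.0
    if truth.missing.get("ema", False):
        return None
    perceived_h = (truth.true_tst_min + bias_min + noise) / 60.0
    return {
        "participant": truth.participant,
        "date": pd.Timestamp(truth.date + dt.timedelta(days=1)),
        "category": bin_tst_category(perceived_h),
    }


def profiles_to_demographics(profiles) -> pd.DataFrame:
    """Demographics table (participant, age, sex, meq, group) from profiles."""
    return pd.DataFrame(
        {
            "participant": [p.participant for p in profiles],
            "age": [p.age for p in profiles],
            "sex": [p.sex for p in profiles],
            "meq": [p.meq for p in profiles],
            "group": [p.group for p in profiles],
        }
    )


def simulate_cohort(
    config: CohortConfig,
    params: dict | None = None,
    *,
    render_bed_stream: bool = True,
) -> SimulatedCohort:
    """Generate truth and render all four raw streams for a whole cohort.

    Deterministic given ``config.seed``.  ``render_bed_stream=False``
    skips the (large, 1 Hz) bed stream for analyses that do not use it.
    """
    p = params or load_default_params()
    profiles, truths = generate_cohort(config, p)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    act_parts, bed_parts, scr_parts, ema_rows = [], [], [], []
    for truth in truths:
        a = render_actigraph(truth, p["render"]["actigraph"], rng)
        if len(a.data):
            act_parts.append(a.data)
        if render_bed_stream:
            b = render_bed(truth, p["render"]["bed"], rng)
            if len(b.data):
                bed_parts.append(b.data)
        s = render_screen(truth, p["render"]["screen"], rng)
        if len(s.data):
            scr_parts.append(s.data)
        e = render_ema(truth, p["ema"]["misperception_sd_min"], rng, p["ema"]["bias_min"])
        if e is not None:
            ema_rows.append(e)

    def _cat(parts, cls, cols):
        if not parts:
            return cls(data=pd.DataFrame(columns=cols))
        return cls(data=pd.concat(parts, ignore_index=True))

    return SimulatedCohort(
        profiles=profiles,
        truths=truths,
        actigraph=_cat(act_parts, EpochLabelStream, ["participant", "timestamp", "label"]),
        bed=_cat(bed_parts, BedStatusStream, ["participant", "timestamp", "status"]),
        screen=_cat(scr_parts, ScreenEventLog, ["participant", "timestamp", "event"]),
        ema=EmaResponseTable(
            data=pd.DataFrame(ema_rows, columns=["participant", "date", "category"])
        ),
        demographics=profiles_to_demographics(profiles),
    )


def write_cohort_csvs(sim: SimulatedCohort, out_dir) -> list:
    """Write the rendered raw streams in the same CSV schemas ingest reads."""
    from pathlib import Path

    from .ingest import write_stream

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, stream in (
        ("actigraph", sim.actigraph),
        ("bed", sim.bed),
        ("screen", sim.screen),
        ("ema", sim.ema),
    ):
        write_stream(stream, out / f"{name}.csv")
        written.append(str(out / f"{name}.csv"))
    sim.demographics.to_csv(out / "demographics.csv", index=False)
    written.append(str(out / "demographics.csv"))
    return written
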