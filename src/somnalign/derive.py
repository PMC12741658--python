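"""Nightly sleep onset/offset/TST derivation from raw streams.

The derivation follows a fixed order for every sensor modality:

1. remove incomplete rows, standardize instants to Europe/Helsinki;
2. turn sleep-marked samples (actigraph REST-S epochs, bed status-1
   seconds) into episodes, merging episodes separated by gaps of up to
   5 minutes; smartphone episodes are the maximal screen-inactivity
   intervals from a lock/off -> unlock/on state machine;
3. assign each episode to a 3 PM -> 3 PM local study day (by its onset);
4. keep the longest episode per participant-day (ties: earliest onset);
5. drop days whose total sleep time falls outside 3-13 h;
6. remove, per modality, the rows holding the k=2 largest onset and
   offset outliers (largest absolute deviation from the column mean,
   union across the two columns).

EMA total sleep time is the midpoint of the reported category; the
morning report on date D describes the night of study day D-1.

All onset/offset arithmetic downstream uses *window-relative minutes*
(minutes since the 15:00 window start), which makes midnight-crossing
averages and deviations well defined; clock strings are presentation only.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import (
    EMA_CATEGORIES,
    EPOCH_SECONDS,
    HELSINKI,
    drop_missing,
    standardize_timezone,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SleepEpisode",
    "extract_label_episodes",
    "infer_screen_inactivity",
    "assign_day_window",
    "window_start",
    "window_relative_minutes",
    "select_main_sleep",
    "apply_tst_filter",
    "ema_to_hours",
    "remove_outliers",
    "build_daily_records",
    "SENSOR_MODALITIES",
]

SENSOR_MODALITIES = ("actigraph", "bed", "smartphone")

#: Numeric hours assigned to each categorical TST answer (bin midpoints;
#: the open-ended bins take half an hour beyond their bound).
EMA_HOURS = {
    "under 5 hours": 4.5,
    "5-6 hours": 5.5,
    "6-7 hours": 6.5,
    "7-8 hours": 7.5,
    "8-9 hours": 8.5,
    "9-10 hours": 9.5,
    "over 10 hours": 10.5,
}


@dataclass(frozen=True)
class SleepEpisode:
    """One contiguous inferred sleep interval."""

    participant: str
    modality: str
    onset: pd.Timestamp
    offset: pd.Timestamp

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("offset must be after onset")

    @property
    def duration_min(self) -> float:
        return (self.offset - self.onset).total_seconds() / 60.0

    @property
    def study_day(self) -> dt.date:
        return assign_day_window(self.onset)


def _merge_marked_samples(times: pd.DatetimeIndex, sample_seconds: int, gap_threshold_min: float):
    """Merge sorted sleep-marked sample intervals, closing gaps <= threshold.

    Each marked sample covers ``[t, t + sample_seconds)``.  Two consecutive
    marked intervals whose gap (next start minus previous end) is at most
    the threshold belong to the same episode; the gap counts toward the
    episode's span.  Returns a list of (onset, offset) pairs.
    """
    if len(times) == 0:
        return []
    starts = times.asi8  # ns since epoch
    step = int(sample_seconds * 1e9)
    ends = starts + step
    gap_ns = int(round(gap_threshold_min * 60 * 1e9))
    breaks = np.flatnonzero(starts[1:] - ends[:-1] > gap_ns) + 1
    run_starts = np.concatenate(([0], breaks))
    run_ends = np.concatenate((breaks, [len(starts)]))  # exclusive
    tz = times.tz
    return [
        (
            pd.Timestamp(starts[i], unit="ns", tz="UTC").tz_convert(tz),
            pd.Timestamp(ends[j - 1], unit="ns", tz="UTC").tz_convert(tz),
        )
        for i, j in zip(run_starts, run_ends)
    ]


def extract_label_episodes(stream, sleep_marker=None, gap_threshold_min: float = 5.0):
    """Sleep episodes from an epoch-label (actigraph) or bed-status stream.

    ``sleep_marker`` defaults to ``"REST-S"`` for the actigraph and status
    ``1`` for the bed sensor.  Episode onset is the first marked sample
    start; offset is the end of the last marked sample (start + epoch
    length).  Gaps of up to ``gap_threshold_min`` minutes between marked
    runs are absorbed into a single episode.

    Returns a list of ``SleepEpisode`` per participant in the stream.
    """
    if stream.schema not in EPOCH_SECONDS:
        raise ValueError(f"expected actigraph or bed stream, got {stream.schema!r}")
    if sleep_marker is None:
        sleep_marker = "REST-S" if stream.schema == "actigraph" else 1
    modality = "actigraph" if stream.schema == "actigraph" else "bed"
    step = EPOCH_SECONDS[stream.schema]

    episodes = []
    df = stream.data
    marked = df[df[stream.value_col] == sleep_marker]
    for pid, sub in marked.groupby("participant", sort=True):
        times = pd.DatetimeIndex(sub[stream.time_col])
        for onset, offset in _merge_marked_samples(times, step, gap_threshold_min):
            episodes.append(SleepEpisode(pid, modality, onset, offset))
    return episodes


def infer_screen_inactivity(log):
    """Maximal screen-inactivity intervals from a smartphone event log.

    A two-state machine: ``lock``/``off`` enter the inactive state,
    ``unlock``/``on`` return to active.  Redundant repeated events are
    ignored (the first lock of a lock,lock,unlock run opens the interval).
    A log starting mid-state opens at its first observed transition —
    nothing is extrapolated before the first event.

    Returns ``{participant: [(start, end), ...]}``.
    """
    if log.schema != "screen":
        raise ValueError(f"expected screen log, got {log.schema!r}")
    closes = {"lock", "off"}
    out: dict[str, list] = {}
    for pid, sub in log.data.groupby("participant", sort=True):
        intervals = []
        state = None  # unknown until first event
        opened = None
        for t, ev in zip(sub[log.time_col], sub[log.value_col]):
            want = "inactive" if ev in closes else "active"
            if want == state:
                continue
            if want == "inactive":
                opened = t
            elif state == "inactive" and opened is not None and t > opened:
                intervals.append((opened, t))
            state = want
        out[pid] = intervals
    return out


def window_start(study_day: dt.date) -> pd.Timestamp:
    """The 15:00 local wall-clock instant opening a study day's window."""
    return pd.Timestamp(dt.datetime.combine(study_day, dt.time(15, 0)), tz=HELSINKI)


def assign_day_window(instant: pd.Timestamp) -> dt.date:
    """Map an instant to its 3 PM -> 3 PM study day (local wall clock).

    The window ``[15:00 of day D, 15:00 of day D+1)`` belongs to day D, so
    a 02:00 instant on Jan 2 belongs to study day Jan 1 and 15:00:00 sharp
    opens a new day.
    """
    if instant.tzinfo is None:
        raise ValueError("assign_day_window requires a timezone-aware instant")
    local = instant.tz_convert(HELSINKI) if hasattr(instant, "tz_convert") else instant.astimezone(HELSINKI)
    d = local.date()
    return d if local.time() >= dt.time(15, 0) else d - dt.timedelta(days=1)


def window_relative_minutes(instant: pd.Timestamp, study_day: dt.date) -> float:
    """Minutes elapsed from the study day's 15:00 window start."""
    return (instant - window_start(study_day)).total_seconds() / 60.0


def select_main_sleep(candidates):
    """The longest candidate episode; ties break to the earliest onset.

    ``candidates`` may be ``SleepEpisode`` objects or plain
    ``(onset, offset)`` pairs; returns ``None`` when empty.
    """
    best = None
    best_key = None
    for c in candidates:
        onset, offset = (c.onset, c.offset) if isinstance(c, SleepEpisode) else c
        dur = (offset - onset).total_seconds()
        key = (-dur, onset)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return best


def apply_tst_filter(tst_min: float, lower_min: float = 180.0, upper_min: float = 780.0) -> bool:
    """True iff a total sleep time is plausible (3-13 h, bounds inclusive)."""
    return lower_min <= tst_min <= upper_min


def ema_to_hours(category: str) -> float:
    """Numeric hours for a categorical TST answer (e.g. "6-7 hours" -> 6.5)."""
    try:
        return EMA_HOURS[category]
    except KeyError:
        raise ValueError(
            f"unknown EMA category {category!r}; expected one of {list(EMA_CATEGORIES)}"
        ) from None


def remove_outliers(daily: pd.DataFrame, k: int = 2):
    """Remove the rows carrying the k largest onset and offset outliers.

    Outlyingness per column is the absolute deviation from that column's
    mean on the window-relative minute scale.  The k most deviant rows are
    flagged in each of the onset and offset columns and the union removed
    (a row flagged by both columns is removed once).  Ties break by first
    occurrence.  Tables with <= k rows are returned untouched with a
    warning.

    Returns ``(kept, removed)`` DataFrames.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if len(daily) <= k or k == 0:
        if 0 < len(daily) <= k:
            warnings.warn(f"table has {len(daily)} rows <= k={k}; no outlier removal", stacklevel=2)
        return daily.copy(), daily.iloc[0:0].copy()
    flagged: set[int] = set()
    for col in ("onset_rel_min", "offset_rel_min"):
        x = daily[col].to_numpy(dtype=float)
        dev = np.abs(x - x.mean())
        order = np.argsort(-dev, kind="stable")  # stable: ties -> first occurrence
        flagged.update(daily.index[order[:k]])
    keep_mask = ~daily.index.isin(list(flagged))
    return daily[keep_mask].copy(), daily[~keep_mask].copy()


def _sensor_daily_rows(pid, modality, intervals, tst_bounds, attrition):
    """Window, select and TST-filter one participant-modality interval set."""
    by_day: dict[dt.date, list] = {}
    for onset, offset in intervals:
        if offset <= onset:
            warnings.warn(f"dropping non-positive interval for {pid}", stacklevel=2)
            continue
        by_day.setdefault(assign_day_window(onset), []).append((onset, offset))
    rows = []
    for day, cands in sorted(by_day.items()):
        onset, offset = select_main_sleep(cands)
        tst = (offset - onset).total_seconds() / 60.0
        if not apply_tst_filter(tst, *tst_bounds):
            attrition["tst_filtered"] += 1
            continue
        rows.append(
            {
                "participant": pid,
                "study_day": day,
                "modality": modality,
                "onset": onset,
                "offset": offset,
                "tst_min": tst,
                "onset_rel_min": window_relative_minutes(onset, day),
                "offset_rel_min": window_relative_minutes(offset, day),
            }
        )
    return rows


def build_daily_records(
    actigraph=None,
    bed=None,
    screen=None,
    ema=None,
    *,
    gap_threshold_min: float = 5.0,
    tst_bounds: tuple[float, float] = (180.0, 780.0),
    outlier_k: int = 2,
    assume_tz: str | None = None,
):
    """Run the full derivation on ingested streams.

    Applies, in order: missing-row removal, timezone standardization,
    episode extraction / inactivity inference, 3 PM windowing, longest-
    episode selection, the 3-13 h TST filter, and per-modality outlier
    removal.

    Returns ``(daily, removed, attrition)`` where ``daily`` is a long
    table with one row per surviving participant-day-modality (EMA rows
    carry TST only), ``removed`` holds the outlier-removed rows, and
    ``attrition`` counts removals per stage.
    """
    attrition = {"missing_rows": 0, "tst_filtered": 0, "outlier_rows": 0}
    rows: list[dict] = []

    for stream, modality in ((actigraph, "actigraph"), (bed, "bed")):
        if stream is None or len(stream) == 0:
            continue
        clean = drop_missing(stream)
        attrition["missing_rows"] += clean.n_removed
        clean = standardize_timezone(clean, assume_tz)
        episodes = extract_label_episodes(clean, gap_threshold_min=gap_threshold_min)
        by_pid: dict[str, list] = {}
        for ep in episodes:
            by_pid.setdefault(ep.participant, []).append((ep.onset, ep.offset))
        for pid, intervals in sorted(by_pid.items()):
            rows.extend(_sensor_daily_rows(pid, modality, intervals, tst_bounds, attrition))

    if screen is not None and len(screen) > 0:
        clean = drop_missing(screen)
        attrition["missing_rows"] += clean.n_removed
        clean = standardize_timezone(clean, assume_tz)
        for pid, intervals in infer_screen_inactivity(clean).items():
            rows.extend(_sensor_daily_rows(pid, "smartphone", intervals, tst_bounds, attrition))

    if ema is not None and len(ema) > 0:
        clean = drop_missing(ema)
        attrition["missing_rows"] += clean.n_removed
        for _, r in clean.data.iterrows():
            date = r["date"].date() if hasattr(r["date"], "date") else r["date"]
            rows.append(
                {
                    "participant": r["participant"],
                    # the morning report describes the previous night's window
                    "study_day": date - dt.timedelta(days=1),
                    "modality": "ema",
                    "onset": pd.NaT,
                    "offset": pd.NaT,
                    "tst_min": ema_to_hours(r["category"]) * 60.0,
                    "onset_rel_min": np.nan,
                    "offset_rel_min": np.nan,
                }
            )

    columns = [
        "participant",
        "study_day",
        "modality",
        "onset",
        "offset",
        "tst_min",
        "onset_rel_min",
        "offset_rel_min",
    ]
    daily = pd.DataFrame(rows, columns=columns)
    removed_parts = []
    kept_parts = []
    for modality, sub in daily.groupby("modality", sort=True):
        if modality in SENSOR_MODALITIES and len(sub) > 0:
            kept, removed = remove_outliers(sub, k=outlier_k)
            kept_parts.append(kept)
            removed_parts.append(removed)
        else:
            kept_parts.append(sub)
    if kept_parts:
        daily = pd.concat(kept_parts).sort_values(
            ["participant", "study_day", "modality"], kind="stable"
        )
        daily = daily.reset_index(drop=True)
    removed = (
        pd.concat(removed_parts).reset_index(drop=True)
        if removed_parts
        else daily.iloc[0:0].copy()
    )
    attrition["outlier_rows"] = len(removed)
    logger.info("derivation attrition: %s", attrition)
    return daily, removed, attrition
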