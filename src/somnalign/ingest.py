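"""Reading, validation and timezone standardization of the four raw streams.

The pipeline consumes four delimited text streams per participant:

* ``actigraph`` — 30-second epoch activity labels in {ACTIVE, REST, REST-S};
  REST-S marks sustained low activity, i.e. probable sleep.
* ``bed`` — 1 Hz ballistocardiographic bed-sensor status codes in {0,1,2,3};
  status 1 means "occupied and asleep", 0/2/3 are non-sleep states
  (out of bed, awake in bed, signal overload).
* ``screen`` — smartphone screen events in {on, off, lock, unlock}.
* ``ema`` — morning self-report of last night's sleep duration as one of
  seven categories ("under 5 hours" ... "over 10 hours").

All timestamps are standardized to Europe/Helsinki before any windowing so
that the 3 PM day boundaries fall on local wall-clock time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from zoneinfo import ZoneInfo

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HELSINKI",
    "ACTIGRAPH_LABELS",
    "BED_STATUSES",
    "SCREEN_EVENTS",
    "EMA_CATEGORIES",
    "EpochLabelStream",
    "BedStatusStream",
    "ScreenEventLog",
    "EmaResponseTable",
    "read_stream",
    "read_demographics",
    "standardize_timezone",
    "drop_missing",
    "write_stream",
]

HELSINKI = ZoneInfo("Europe/Helsinki")

ACTIGRAPH_LABELS = frozenset({"ACTIVE", "REST", "REST-S"})
BED_STATUSES = frozenset({0, 1, 2, 3})
SCREEN_EVENTS = frozenset({"on", "off", "lock", "unlock"})
EMA_CATEGORIES = (
    "under 5 hours",
    "5-6 hours",
    "6-7 hours",
    "7-8 hours",
    "8-9 hours",
    "9-10 hours",
    "over 10 hours",
)

EPOCH_SECONDS = {"actigraph": 30, "bed": 1}

#: CSV schema: name -> (time column, value column, allowed values or None)
SCHEMAS = {
    "actigraph": ("timestamp", "label", ACTIGRAPH_LABELS),
    "bed": ("timestamp", "status", BED_STATUSES),
    "screen": ("timestamp", "event", SCREEN_EVENTS),
    "ema": ("date", "category", frozenset(EMA_CATEGORIES)),
}


@dataclass
class _Stream:
    """Base container: a participant-keyed, time-ordered event table."""

    schema: str = field(init=False, default="")
    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def time_col(self) -> str:
        return SCHEMAS[self.schema][0]

    @property
    def value_col(self) -> str:
        return SCHEMAS[self.schema][1]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class EpochLabelStream(_Stream):
    schema = "actigraph"


@dataclass
class BedStatusStream(_Stream):
    schema = "bed"


@dataclass
class ScreenEventLog(_Stream):
    schema = "screen"


@dataclass
class EmaResponseTable(_Stream):
    schema = "ema"


_STREAM_CLASSES = {
    "actigraph": EpochLabelStream,
    "bed": BedStatusStream,
    "screen": ScreenEventLog,
    "ema": EmaResponseTable,
}


def _parse_timestamps(raw: pd.Series, assume_tz: str | None) -> pd.Series:
    """Parse ISO-8601 timestamps; localize naive ones with ``assume_tz``.

    Missing entries stay NaT (they are removed later by ``drop_missing``);
    a present but unparseable entry is a hard error naming the row.
    """
    present = raw.notna() & (raw.astype(str).str.strip() != "")
    parsed = pd.to_datetime(raw.where(present), errors="coerce", utc=True, format="ISO8601")
    bad = present & parsed.isna()
    if bad.any():
        row = bad.idxmax()
        raise ValueError(f"unparseable timestamp at row {row}: {raw[row]!r}")

    # utc=True localizes naive stamps as UTC, which is wrong for naive input;
    # detect naive input by reparsing without coercion to a zone (mixed
    # offsets come back as object dtype, i.e. zone-aware input).
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        naive = pd.to_datetime(raw.where(present), errors="coerce", format="ISO8601")
    if naive.dtype == "datetime64[ns]" and present.any():
        if assume_tz is None:
            raise ValueError(
                "naive timestamps found and no assumed timezone supplied; "
                "pass assume_tz (e.g. 'Europe/Helsinki')"
            )
        parsed = naive.dt.tz_localize(ZoneInfo(assume_tz))
    return parsed


def read_stream(path, schema_name: str, assume_tz: str | None = None):
    """Read one raw stream CSV into its validated, sorted stream type.

    Unknown labels/statuses/events are hard errors naming the offending
    value and row. Duplicate timestamps keep the first occurrence (warn).
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; expected one of {sorted(SCHEMAS)}")
    time_col, value_col, allowed = SCHEMAS[schema_name]
    df = pd.read_csv(path, dtype=str)
    expected = ["participant", time_col, value_col]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: header {list(df.columns)} does not match schema {expected}")

    if schema_name == "ema":
        dates = pd.to_datetime(df[time_col], errors="coerce")
        bad = df[time_col].notna() & dates.isna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(f"unparseable date at row {row}: {df.loc[row, time_col]!r}")
        df[time_col] = dates
    else:
        df[time_col] = _parse_timestamps(df[time_col], assume_tz)

    values = df[value_col]
    if schema_name == "bed":
        numeric = pd.to_numeric(values, errors="coerce")
        known = values.isna() | numeric.isin(list(BED_STATUSES))
        df[value_col] = numeric.astype("Int64")
    else:
        known = values.isna() | values.isin(list(allowed))
    if not known.all():
        row = (~known).idxmax()
        raise ValueError(
            f"unknown {value_col} value {values[row]!r} at row {row} (schema {schema_name!r})"
        )

    df = df.sort_values(["participant", time_col], kind="stable").reset_index(drop=True)

    dup = df.duplicated(["participant", time_col]) & df[time_col].notna()
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate timestamps in {schema_name} stream; keeping first",
            stacklevel=2,
        )
        df = df[~dup].reset_index(drop=True)

    return _STREAM_CLASSES[schema_name](data=df)


def read_demographics(path) -> pd.DataFrame:
    """Read the demographics table (participant, age, sex, meq, group)."""
    df = pd.read_csv(path)
    expected = ["participant", "age", "sex", "meq", "group"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: header {list(df.columns)} does not match {expected}")
    bad_group = ~df["group"].isin(["control", "MDD", "BD", "BPD"])
    if bad_group.any():
        raise ValueError(f"unknown group value {df.loc[bad_group.idxmax(), 'group']!r}")
    return df


def standardize_timezone(stream, assume_tz: str | None = None):
    """Express all instants in Europe/Helsinki without moving them in time.

    Timezone-aware instants are converted (identical absolute time, local
    wall clock including DST offsets +02:00/+03:00); naive instants require
    an explicit assumed zone.
    """
    df = stream.data.copy()
    col = stream.time_col
    if stream.schema == "ema":
        return type(stream)(data=df)  # calendar dates carry no zone
    times = df[col]
    tz = getattr(times.dtype, "tz", None)
    if tz is None:
        if times.notna().any() and assume_tz is None:
            raise ValueError("naive timestamps: supply assume_tz to standardize_timezone")
        if assume_tz is not None:
            times = times.dt.tz_localize(ZoneInfo(assume_tz))
    df[col] = times.dt.tz_convert(HELSINKI)
    return type(stream)(data=df)


def drop_missing(stream):
    """Remove rows with an absent timestamp or value; log the removal count."""
    df = stream.data
    keep = df[stream.time_col].notna() & df[stream.value_col].notna()
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("drop_missing: removed %d incomplete rows (%s)", n_removed, stream.schema)
    out = type(stream)(data=df[keep].reset_index(drop=True))
    out.n_removed = n_removed
    return out


def write_stream(stream, path) -> None:
    """Write a stream back to its CSV schema (ISO-8601 timestamps)."""
    df = stream.data.copy()
    col = stream.time_col
    if stream.schema == "ema":
        df[col] = df[col].dt.strftime("%Y-%m-%d")
    else:
        df[col] = df[col].map(lambda t: t.isoformat() if pd.notna(t) else "")
    df.to_csv(path, index=False)
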