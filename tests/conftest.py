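import datetime as dt

import numpy as np
import pandas as pd
import pytest

from somnalign.derive import window_start
from somnalign.ingest import (
    HELSINKI,
    BedStatusStream,
    EmaResponseTable,
    EpochLabelStream,
    ScreenEventLog,
)


def ts(s: str) -> pd.Timestamp:
    """Helsinki-local timestamp from 'YYYY-mm-dd HH:MM[:SS]'."""
    return pd.Timestamp(s, tz=HELSINKI)


def make_actigraph(pid, start, labels, step_s=30) -> EpochLabelStream:
    """Epoch stream from a label sequence starting at ``start``."""
    times = pd.date_range(start, periods=len(labels), freq=f"{step_s}s")
    return EpochLabelStream(
        data=pd.DataFrame({"participant": pid, "timestamp": times, "label": list(labels)})
    )


def make_bed(pid, start, statuses) -> BedStatusStream:
    times = pd.date_range(start, periods=len(statuses), freq="1s")
    return BedStatusStream(
        data=pd.DataFrame({"participant": pid, "timestamp": times, "status": list(statuses)})
    )


def make_screen(pid, events) -> ScreenEventLog:
    """Event log from [(timestamp-string-or-ts, event), ...]."""
    rows = [(t if isinstance(t, pd.Timestamp) else ts(t), e) for t, e in events]
    return ScreenEventLog(
        data=pd.DataFrame(
            {
                "participant": pid,
                "timestamp": [r[0] for r in rows],
                "event": [r[1] for r in rows],
            }
        )
    )


def make_ema(pid, rows) -> EmaResponseTable:
    """EMA table from [(date-string, category), ...]."""
    return EmaResponseTable(
        data=pd.DataFrame(
            {
                "participant": pid,
                "date": [pd.Timestamp(d) for d, _ in rows],
                "category": [c for _, c in rows],
            }
        )
    )


def actigraph_spanning(pid, day: dt.date, onset_rel_min, offset_rel_min, fill="ACTIVE"):
    """Full-window actigraph stream with REST-S over [onset, offset)."""
    w0 = window_start(day)
    grid = pd.date_range(w0, window_start(day + dt.timedelta(days=1)), freq="30s", inclusive="left")
    onset = w0 + pd.Timedelta(minutes=onset_rel_min)
    offset = w0 + pd.Timedelta(minutes=offset_rel_min)
    labels = np.where((grid >= onset) & (grid < offset), "REST-S", fill)
    return EpochLabelStream(
        data=pd.DataFrame({"participant": pid, "timestamp": grid, "label": labels})
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
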