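"""Episode extraction, windowing, selection, filters — against oracles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from somnalign.derive import (
    SleepEpisode,
    apply_tst_filter,
    assign_day_window,
    build_daily_records,
    ema_to_hours,
    extract_label_episodes,
    infer_screen_inactivity,
    remove_outliers,
    select_main_sleep,
    window_start,
)
from somnalign.ingest import HELSINKI

from conftest import actigraph_spanning, make_actigraph, make_bed, make_ema, make_screen, ts


# ---------------------------------------------------------------- oracles


def second_scan_episodes(marked_starts, step_s, gap_min):
    """Brute-force oracle: paint sleep seconds on a second grid, close
    non-sleep gaps of <= gap_min minutes, report maximal runs."""
    if len(marked_starts) == 0:
        return []
    t0 = int(min(marked_starts).timestamp())
    t1 = int(max(marked_starts).timestamp()) + step_s
    asleep = np.zeros(t1 - t0, dtype=bool)
    for s in marked_starts:
        i = int(s.timestamp()) - t0
        asleep[i : i + step_s] = True
    # close internal gaps of <= gap_min minutes
    gap_s = int(gap_min * 60)
    i = 0
    n = len(asleep)
    while i < n:
        if not asleep[i]:
            j = i
            while j < n and not asleep[j]:
                j += 1
            interior = i > 0 and j < n
            if interior and j - i <= gap_s:
                asleep[i:j] = True
            i = j
        else:
            i += 1
    runs = []
    i = 0
    tz = marked_starts[0].tz
    while i < n:
        if asleep[i]:
            j = i
            while j < n and asleep[j]:
                j += 1
            runs.append(
                (
                    pd.Timestamp(t0 + i, unit="s", tz="UTC").tz_convert(tz),
                    pd.Timestamp(t0 + j, unit="s", tz="UTC").tz_convert(tz),
                )
            )
            i = j
        else:
            i += 1
    return runs


def state_replay_intervals(events):
    """Screen-inactivity oracle: for every event time, determine the state
    by scanning all preceding events, then pair the transitions."""

    def state_at(t, inclusive):
        last = None
        for et, ev in events:
            if et < t or (inclusive and et == t):
                last = ev
        if last is None:
            return None
        return "inactive" if last in ("lock", "off") else "active"

    intervals = []
    opened = None
    for et, _ in events:
        before = state_at(et, inclusive=False)
        after = state_at(et, inclusive=True)
        if before != after:
            if after == "inactive":
                opened = et
            elif opened is not None and et > opened:
                intervals.append((opened, et))
                opened = None
    return intervals


# ------------------------------------------------------ episode extraction


def test_single_rest_s_run_matches_worked_example():
    """A REST-S run from 23:55 to 06:51 yields exactly that episode."""
    labels = ["ACTIVE"] * 10 + ["REST-S"] * (2 * (5 + 6 * 60 + 51)) + ["ACTIVE"] * 10
    stream = make_actigraph("P01", ts("2019-01-01 23:50:00"), labels)
    eps = extract_label_episodes(stream)
    assert len(eps) == 1
    assert eps[0].onset == ts("2019-01-01 23:55:00")
    assert eps[0].offset == ts("2019-01-02 06:51:00")


@pytest.mark.parametrize(
    "gap_min, n_expected", [(4, 1), (5, 1), (6, 2)]  # rule is inclusive at 5
)
def test_gap_merge_threshold(gap_min, n_expected):
    labels = ["REST-S"] * 20 + ["ACTIVE"] * (2 * gap_min) + ["REST-S"] * 20
    stream = make_actigraph("P01", ts("2019-01-02 00:00:00"), labels)
    eps = extract_label_episodes(stream)
    assert len(eps) == n_expected
    if n_expected == 1:
        assert eps[0].onset == ts("2019-01-02 00:00:00")
        assert eps[0].offset == ts("2019-01-02 00:" + f"{20 + gap_min:02d}:00")


def test_bed_status_one_run_with_short_overload():
    """A <=5-min status-3 burst inside a status-1 run stays one episode."""
    statuses = [1] * 600 + [3] * 240 + [1] * 600
    stream = make_bed("P01", ts("2019-01-02 00:00:00"), statuses)
    eps = extract_label_episodes(stream)
    assert len(eps) == 1
    assert eps[0].duration_min == pytest.approx(24.0)


def test_empty_stream_yields_no_episodes():
    stream = make_actigraph("P01", ts("2019-01-02 00:00:00"), [])
    assert extract_label_episodes(stream) == []


def test_random_streams_match_second_scan_oracle(rng):
    """Episode extraction equals the per-second brute-force scanner."""
    for _ in range(60):
        n = int(rng.integers(5, 500))
        labels = rng.choice(["ACTIVE", "REST", "REST-S"], size=n, p=[0.3, 0.2, 0.5])
        stream = make_actigraph("P01", ts("2019-01-01 20:00:00"), list(labels))
        got = [(e.onset, e.offset) for e in extract_label_episodes(stream)]
        marked = [t for t, lab in zip(stream.data["timestamp"], labels) if lab == "REST-S"]
        assert got == second_scan_episodes(marked, 30, 5.0)


# ------------------------------------------------------- screen inactivity


def test_single_lock_unlock_pair():
    log = make_screen("P01", [("2019-01-01 23:00", "lock"), ("2019-01-02 07:00", "unlock")])
    assert infer_screen_inactivity(log)["P01"] == [
        (ts("2019-01-01 23:00"), ts("2019-01-02 07:00"))
    ]


def test_duplicate_locks_open_at_first():
    log = make_screen(
        "P01",
        [
            ("2019-01-01 23:00", "lock"),
            ("2019-01-01 23:30", "lock"),
            ("2019-01-02 07:00", "unlock"),
        ],
    )
    assert infer_screen_inactivity(log)["P01"] == [
        (ts("2019-01-01 23:00"), ts("2019-01-02 07:00"))
    ]


def test_log_starting_mid_state_opens_at_first_transition():
    """An initial unlock implies we were inactive before, but nothing is
    extrapolated: the first interval opens at the first observed lock."""
    log = make_screen(
        "P01",
        [
            ("2019-01-01 22:00", "unlock"),
            ("2019-01-01 23:00", "lock"),
            ("2019-01-02 07:00", "on"),
        ],
    )
    assert infer_screen_inactivity(log)["P01"] == [
        (ts("2019-01-01 23:00"), ts("2019-01-02 07:00"))
    ]


def test_random_event_sequences_match_state_replay_oracle(rng):
    for _ in range(60):
        n = int(rng.integers(1, 40))
        t0 = ts("2019-01-01 12:00")
        # strictly increasing times; simultaneous-event semantics are
        # pinned separately by the duplicate-event tests
        times = sorted(t0 + pd.Timedelta(minutes=int(m)) for m in rng.choice(2000, size=n, replace=False))
        events = [(t, str(rng.choice(["on", "off", "lock", "unlock"]))) for t in times]
        log = make_screen("P01", events)
        assert infer_screen_inactivity(log)["P01"] == state_replay_intervals(events)


# ------------------------------------------------------------- day windows


def test_early_morning_belongs_to_previous_day():
    assert assign_day_window(ts("2019-01-02 02:00")) == dt.date(2019, 1, 1)


def test_three_pm_sharp_opens_new_day():
    assert assign_day_window(ts("2019-01-02 15:00:00")) == dt.date(2019, 1, 2)
    assert assign_day_window(ts("2019-01-02 14:59:59")) == dt.date(2019, 1, 1)


def test_windows_partition_time_across_dst_transition():
    """Every minute of the spring-forward week maps into exactly one
    window: window_start(day) <= t < window_start(day + 1)."""
    t = pd.Timestamp("2019-03-28 00:00", tz="UTC")
    end = pd.Timestamp("2019-04-03 00:00", tz="UTC")
    while t < end:
        day = assign_day_window(t)
        assert window_start(day) <= t < window_start(day + dt.timedelta(days=1))
        t += pd.Timedelta(minutes=1)


# -------------------------------------------------------- main sleep + TST


def test_longest_candidate_wins():
    a = (ts("2019-01-01 23:00"), ts("2019-01-02 06:00"))  # 420 min
    b = (ts("2019-01-02 03:00"), ts("2019-01-02 03:35"))  # 35 min
    assert select_main_sleep([b, a]) == a


def test_duration_tie_breaks_to_earliest_onset():
    a = (ts("2019-01-01 23:00"), ts("2019-01-02 05:40"))
    b = (ts("2019-01-02 01:00"), ts("2019-01-02 07:40"))
    assert select_main_sleep([b, a]) == a


def test_selection_matches_argmax_oracle(rng):
    base = ts("2019-01-01 15:00")
    for _ in range(50):
        n = int(rng.integers(1, 8))
        cands = []
        for _ in range(n):
            s = int(rng.integers(0, 1200))
            d = int(rng.integers(1, 600))
            cands.append((base + pd.Timedelta(minutes=s), base + pd.Timedelta(minutes=s + d)))
        oracle = min(cands, key=lambda c: (-(c[1] - c[0]).total_seconds(), c[0]))
        assert select_main_sleep(cands) == oracle


@pytest.mark.parametrize(
    "tst, keep", [(179, False), (180, True), (480, True), (780, True), (781, False)]
)
def test_tst_filter_bounds_inclusive(tst, keep):
    assert apply_tst_filter(tst) is keep


# --------------------------------------------------------------------- EMA


@pytest.mark.parametrize(
    "category, hours",
    [
        ("under 5 hours", 4.5),
        ("5-6 hours", 5.5),
        ("6-7 hours", 6.5),
        ("7-8 hours", 7.5),
        ("8-9 hours", 8.5),
        ("9-10 hours", 9.5),
        ("over 10 hours", 10.5),
    ],
)
def test_ema_category_midpoints(category, hours):
    assert ema_to_hours(category) == hours


def test_unknown_ema_category_rejected():
    with pytest.raises(ValueError, match="6 to 7"):
        ema_to_hours("6 to 7 hours")


# ------------------------------------------------------------ outlier rule


def _daily_frame(onsets, offsets):
    return pd.DataFrame(
        {
            "participant": [f"P{i}" for i in range(len(onsets))],
            "onset_rel_min": onsets,
            "offset_rel_min": offsets,
        }
    )


def test_outliers_are_largest_absolute_deviations():
    df = _daily_frame([0, 1, 2, 240, -300], [500, 501, 502, 503, 504])
    kept, removed = remove_outliers(df, k=2)
    # rank |x - mean| oracle for the onset column: mean = -11.4
    dev = (df["onset_rel_min"] - df["onset_rel_min"].mean()).abs()
    worst = set(dev.nlargest(2).index)
    assert worst == {3, 4}
    assert set(removed["onset_rel_min"]).issuperset({240, -300})


def test_row_flagged_by_both_columns_removed_once():
    df = _daily_frame([0, 0, 0, 0, 900], [500, 500, 500, 500, 1400])
    kept, removed = remove_outliers(df, k=1)
    assert len(removed) == 1 and removed.iloc[0]["participant"] == "P4"
    assert len(kept) == 4


def test_identical_values_tie_break_is_first_occurrence():
    df = _daily_frame([5, 5, 5, 5], [7, 7, 7, 7])
    kept1, removed1 = remove_outliers(df, k=2)
    kept2, removed2 = remove_outliers(df, k=2)
    pd.testing.assert_frame_equal(removed1, removed2)
    assert list(removed1.index) == [0, 1]


def test_small_table_not_trimmed():
    df = _daily_frame([0, 500], [600, 700])
    with pytest.warns(UserWarning, match="no outlier removal"):
        kept, removed = remove_outliers(df, k=2)
    assert len(kept) == 2 and len(removed) == 0


# ----------------------------------------------------------- full pipeline


def test_two_hour_episode_filtered_out_of_daily_records():
    stream = actigraph_spanning("P01", dt.date(2019, 1, 1), 540, 660)  # 2 h
    daily, _, attrition = build_daily_records(actigraph=stream, outlier_k=0)
    assert len(daily) == 0
    assert attrition["tst_filtered"] == 1


def test_daily_records_from_all_modalities():
    day = dt.date(2019, 1, 1)
    act = actigraph_spanning("P01", day, 535, 990)
    bed = make_bed("P01", window_start(day) + pd.Timedelta(minutes=530), [1] * (500 * 60))
    scr = make_screen(
        "P01",
        [(window_start(day) + pd.Timedelta(minutes=533), "lock"),
         (window_start(day) + pd.Timedelta(minutes=995), "unlock")],
    )
    ema = make_ema("P01", [("2019-01-02", "7-8 hours")])
    daily, _, _ = build_daily_records(act, bed, scr, ema, outlier_k=0)
    assert set(daily["modality"]) == {"actigraph", "bed", "smartphone", "ema"}
    assert (daily["study_day"] == day).all()
    row = daily.set_index("modality")
    assert row.loc["actigraph", "tst_min"] == pytest.approx(455.0)
    assert row.loc["bed", "tst_min"] == pytest.approx(500.0)
    assert row.loc["smartphone", "tst_min"] == pytest.approx(462.0)
    assert row.loc["ema", "tst_min"] == pytest.approx(450.0)
    assert pd.isna(row.loc["ema", "onset_rel_min"])
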