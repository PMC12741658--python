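"""Cross-modality agreement statistics.

Agreement between each pair of sleep measurement modalities is quantified
the standard way for method-comparison studies:

* **Bland-Altman**: per-participant differences ``d_i = A_i - B_i`` give a
  mean bias, the 95% limits of agreement ``bias ± 1.96·SD(d)`` and a
  t-based CI for the bias.  The pair label "A vs B" always means A − B,
  so a positive onset bias means modality A reports later onsets.
* **Paired t-test** on the differences (two-sided).
* **Pearson correlation** with a Fisher-z 95% CI, gated (reported, never
  blocking) by a Shapiro-Wilk normality check, and classified by the
  Mukaka magnitude bands (negligible < 0.30 ≤ low < 0.50 ≤ moderate
  < 0.70 ≤ high).

Participants are first aggregated by averaging across days on the
window-relative minute scale; a day-level variant is available for the
mixed-model table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ONSET_OFFSET_PAIRS",
    "TST_PAIRS",
    "PairedAgreement",
    "summarize_participants",
    "render_clock",
    "bland_altman",
    "paired_t",
    "pearson_ci",
    "classify_correlation",
    "shapiro_check",
    "agreement_by_group",
]

#: Modality pairs tabulated per metric ("A vs B" == A − B).
ONSET_OFFSET_PAIRS = (
    ("actigraph", "bed"),
    ("smartphone", "bed"),
    ("actigraph", "smartphone"),
)
TST_PAIRS = ONSET_OFFSET_PAIRS + (
    ("actigraph", "ema"),
    ("ema", "bed"),
    ("ema", "smartphone"),
)

_METRIC_COL = {"onset": "onset_rel_min", "offset": "offset_rel_min", "tst": "tst_min"}


@dataclass
class PairedAgreement:
    """Bland-Altman + paired-t + Pearson summary for one modality pair."""

    metric: str
    pair: tuple[str, str]
    group: str
    n: int
    mean_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    t_stat: float
    df: int
    p_two_sided: float
    r: float = math.nan
    r_ci: tuple[float, float] = (math.nan, math.nan)
    r_p: float = math.nan
    r_class: str = ""
    shapiro_w: float = math.nan
    shapiro_p: float = math.nan
    degenerate: bool = False
    points: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def summarize_participants(daily: pd.DataFrame) -> pd.DataFrame:
    """Average each participant-modality across days (window-relative scale).

    Returns one row per participant-modality with mean onset/offset
    (window-relative minutes), mean TST (minutes) and the day count.
    """
    g = daily.groupby(["participant", "modality"], sort=True)
    out = g.agg(
        mean_onset_rel=("onset_rel_min", "mean"),
        mean_offset_rel=("offset_rel_min", "mean"),
        mean_tst=("tst_min", "mean"),
        n_days=("tst_min", "size"),
    ).reset_index()
    return out


def render_clock(rel_min: float, window_start_hour: int = 15) -> str:
    """Clock string for a window-relative minute value (wraps modulo 24 h)."""
    total = (window_start_hour * 60 + rel_min) % 1440
    h, m = divmod(int(round(total)), 60)
    return f"{h % 24:02d}:{m:02d}"


def paired_t(differences) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of mean(differences) = 0.

    Returns ``(t, df, p)``; requires n >= 2 and a non-degenerate SD.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired t-test undefined for zero-variance differences")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def pearson_ci(x, y, conf: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """Pearson r with a Fisher-z confidence interval and two-sided p.

    The p-value uses the exact t transform ``t = r sqrt((n-2)/(1-r^2))``;
    the CI uses ``tanh(atanh(r) ± z / sqrt(n-3))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_ci requires two equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("pearson_ci requires finite values")
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("pearson r undefined for a constant sample")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, (r, r), 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    if n > 3:
        z = math.atanh(r)
        half = stats.norm.ppf(0.5 + conf / 2) / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (-1.0, 1.0)
    return r, ci, float(p)


def classify_correlation(r: float) -> str:
    """Mukaka magnitude band of |r|; boundaries take the higher band."""
    a = abs(r)
    if a > 1.0:
        raise ValueError(f"|r| > 1: {r}")
    if a >= 0.70:
        return "high"
    if a >= 0.50:
        return "moderate"
    if a >= 0.30:
        return "low"
    return "negligible"


def shapiro_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a sample (3 <= n <= 5000).

    Reported alongside correlations as a normality gate; the analysis
    proceeds with Pearson regardless of the result.
    """
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def bland_altman(a, b, *, metric: str = "", pair=("A", "B"), group: str = "all") -> PairedAgreement:
    """Bland-Altman agreement for paired per-participant values.

    ``a`` and ``b`` must be aligned arrays (same participants, same order);
    differences are ``a - b``.  With zero-variance differences the limits
    of agreement collapse onto the bias and the result carries a
    ``degenerate`` flag (t-test undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must align")
    n = a.size
    if n < 2:
        raise ValueError("Bland-Altman requires n >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    tq = stats.t.ppf(0.975, n - 1)
    se = sd / math.sqrt(n)
    ci = (bias - tq * se, bias + tq * se)
    degenerate = sd == 0
    if degenerate:
        t_stat, p = math.nan, math.nan
    else:
        t_stat, _, p = paired_t(d)
    res = PairedAgreement(
        metric=metric,
        pair=tuple(pair),
        group=group,
        n=n,
        mean_bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        bias_ci=ci,
        t_stat=t_stat,
        df=n - 1,
        p_two_sided=p,
        degenerate=degenerate,
        points=pd.DataFrame({"mean": (a + b) / 2.0, "diff": d}),
    )
    if n >= 3 and not degenerate:
        try:
            r, r_ci, r_p = pearson_ci(a, b)
        except ValueError:
            pass
        else:
            res.r, res.r_ci, res.r_p = r, r_ci, r_p
            res.r_class = classify_correlation(r)
        try:
            res.shapiro_w, res.shapiro_p = shapiro_check(d)
        except ValueError:
            pass
    return res


def _paired_values(summaries: pd.DataFrame, metric: str, pair, level: str, daily=None):
    """Aligned value arrays for a modality pair (pairwise-complete units)."""
    col = _METRIC_COL[metric]
    if level == "participant":
        wide = summaries.pivot(
            index="participant",
            columns="modality",
            values={"onset": "mean_onset_rel", "offset": "mean_offset_rel", "tst": "mean_tst"}[
                metric
            ],
        )
    elif level == "day":
        wide = daily.pivot_table(
            index=["participant", "study_day"], columns="modality", values=col, aggfunc="first"
        )
    else:
        raise ValueError("level must be 'participant' or 'day'")
    a_mod, b_mod = pair
    if a_mod not in wide.columns or b_mod not in wide.columns:
        return None
    sub = wide[[a_mod, b_mod]].dropna()
    return sub


def agreement_by_group(
    daily: pd.DataFrame,
    demographics: pd.DataFrame,
    *,
    level: str = "participant",
) -> list[PairedAgreement]:
    """The full grid of pairwise comparisons: metric × pair × group.

    Groups are ``all``, ``control`` and ``patients`` (MDD + BD + BPD
    pooled).  Only pairwise-complete units enter each comparison, so n
    varies across pairs.  Groups with fewer than 2 complete pairs are
    omitted with a warning.
    """
    group_of = demographics.set_index("participant")["group"]
    summaries = summarize_participants(daily)
    results = []
    memberships = {
        "all": set(group_of.index),
        "control": set(group_of[group_of == "control"].index),
        "patients": set(group_of[group_of != "control"].index),
    }
    for metric, pairs in (("onset", ONSET_OFFSET_PAIRS), ("offset", ONSET_OFFSET_PAIRS), ("tst", TST_PAIRS)):
        for pair in pairs:
            paired = _paired_values(summaries, metric, pair, level, daily)
            if paired is None:
                continue
            for grp, members in memberships.items():
                pids = paired.index.get_level_values(0) if level == "day" else paired.index
                sub = paired[pids.isin(members)]
                if len(sub) < 2:
                    warnings.warn(
                        f"group {grp!r} has {len(sub)} complete pairs for "
                        f"{metric} {pair}; omitted",
                        stacklevel=2,
                    )
                    continue
                results.append(
                    bland_altman(
                        sub[pair[0]].to_numpy(),
                        sub[pair[1]].to_numpy(),
                        metric=metric,
                        pair=pair,
                        group=grp,
                    )
                )
    return results


def agreement_table(results: list[PairedAgreement]) -> pd.DataFrame:
    """Flatten PairedAgreement results into one row per comparison."""
    rows = []
    for r in results:
        rows.append(
            {
                "metric": r.metric,
                "pair": f"{r.pair[0]} vs {r.pair[1]}",
                "group": r.group,
                "n": r.n,
                "mean_bias": r.mean_bias,
                "sd_diff": r.sd_diff,
                "loa_low": r.loa_low,
                "loa_high": r.loa_high,
                "bias_ci_low": r.bias_ci[0],
                "bias_ci_high": r.bias_ci[1],
                "t": r.t_stat,
                "df": r.df,
                "p": r.p_two_sided,
                "r": r.r,
                "r_ci_low": r.r_ci[0],
                "r_ci_high": r.r_ci[1],
                "r_p": r.r_p,
                "r_class": r.r_class,
                "shapiro_w": r.shapiro_w,
                "shapiro_p": r.shapiro_p,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)
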