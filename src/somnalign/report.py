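"""Pipeline orchestration, attrition accounting and table export.

``run_full_analysis`` chains simulate -> ingest -> derive -> agree ->
model, writes every inter-stage artifact as plain CSV, and records a run
manifest (config hash, seed, per-stage row counts, output files) so a run
is fully reproducible and every removed row is accounted for.

Exported tables mirror the presentation conventions of method-comparison
sleep studies: clock-formatted onset/offset descriptives per modality and
group, an agreement grid (bias, limits of agreement, paired t, Pearson r),
and mixed-model coefficient/variance-component tables.  Display rounding
is half-up to 2 decimals; CSVs keep full precision.
"""

from __future__ import annotations

import datetime as dt
import decimal
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import agreement_by_group, agreement_table, render_clock, summarize_participants
from .derive import build_daily_records
from .ingest import read_demographics, read_stream
from .models import build_model_table, fit_mixed
from .synthetic import CohortConfig, simulate_cohort, write_cohort_csvs

__all__ = ["RunManifest", "run_full_analysis", "export_summary_tables", "round_half_up"]

_MODEL_GRID = [
    ("tst", ("actigraph", "bed")),
    ("tst", ("smartphone", "bed")),
    ("tst", ("actigraph", "smartphone")),
    ("offset", ("actigraph", "bed")),
    ("offset", ("smartphone", "bed")),
    ("offset", ("actigraph", "smartphone")),
    ("onset", ("actigraph", "bed")),
    ("onset", ("smartphone", "bed")),
    ("onset", ("actigraph", "smartphone")),
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention; 0.3396 -> 0.34)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class RunManifest:
    """What a run consumed and produced, stage by stage."""

    config_hash: str
    seed: int
    version: str
    counts: dict = field(default_factory=dict)  # stage -> row counts
    attrition: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _hash_config(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _read_input_dir(input_dir: Path, assume_tz: str | None):
    streams = {}
    for name in ("actigraph", "bed", "screen", "ema"):
        path = input_dir / f"{name}.csv"
        streams[name] = read_stream(path, name, assume_tz=assume_tz) if path.exists() else None
    demo_path = input_dir / "demographics.csv"
    if demo_path.exists():
        demographics = read_demographics(demo_path)
    else:
        raise FileNotFoundError(f"demographics.csv not found in {input_dir}")
    if all(s is None or len(s) == 0 for s in streams.values()):
        raise FileNotFoundError(f"no non-empty stream CSVs found in {input_dir}")
    return streams, demographics


def run_full_analysis(
    out_dir,
    *,
    config: CohortConfig | None = None,
    input_dir=None,
    gap_threshold_min: float = 5.0,
    tst_bounds: tuple[float, float] = (180.0, 780.0),
    outlier_k: int = 2,
    level: str = "participant",
    assume_tz: str | None = None,
    write_raw: bool = False,
) -> RunManifest:
    """Run the whole pipeline and write all stage outputs under ``out_dir``.

    Exactly one of ``config`` (simulate a synthetic cohort) or
    ``input_dir`` (read raw stream CSVs) must be given.
    """
    if (config is None) == (input_dir is None):
        raise ValueError("supply exactly one of config (simulate) or input_dir")
    out = Path(out_dir)

    if config is not None:
        sim = simulate_cohort(config)
        streams = {"actigraph": sim.actigraph, "bed": sim.bed, "screen": sim.screen, "ema": sim.ema}
        demographics = sim.demographics
        seed = config.seed
        cfg_hash = _hash_config(asdict_config(config))
    else:
        streams, demographics = _read_input_dir(Path(input_dir), assume_tz)
        seed = -1
        cfg_hash = _hash_config({"input_dir": str(input_dir)})

    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg_hash, seed=seed, version=__version__)
    manifest.counts["raw_rows"] = {k: (0 if v is None else len(v)) for k, v in streams.items()}

    if config is not None and write_raw:
        raw_dir = out / "raw"
        manifest.outputs += write_cohort_csvs(sim, raw_dir)

    daily, removed, attrition = build_daily_records(
        streams["actigraph"],
        streams["bed"],
        streams["screen"],
        streams["ema"],
        gap_threshold_min=gap_threshold_min,
        tst_bounds=tst_bounds,
        outlier_k=outlier_k,
        assume_tz=assume_tz,
    )
    manifest.attrition = attrition
    manifest.counts["daily_rows"] = len(daily)
    manifest.counts["removed_outlier_rows"] = len(removed)

    daily_out = daily.copy()
    daily_out["onset_iso"] = daily_out.pop("onset").map(
        lambda t: t.isoformat() if pd.notna(t) else ""
    )
    daily_out["offset_iso"] = daily_out.pop("offset").map(
        lambda t: t.isoformat() if pd.notna(t) else ""
    )
    daily_out.to_csv(out / "daily_sleep.csv", index=False)
    removed.to_csv(out / "removed_rows.csv", index=False)
    manifest.outputs += ["daily_sleep.csv", "removed_rows.csv"]

    results = agreement_by_group(daily, demographics, level=level)
    agree = agreement_table(results)
    agree.to_csv(out / "agreement.csv", index=False)
    points = pd.concat(
        [
            r.points.assign(metric=r.metric, pair=f"{r.pair[0]} vs {r.pair[1]}", group=r.group)
            for r in results
        ],
        ignore_index=True,
    ) if results else pd.DataFrame()
    points.to_csv(out / "bland_altman_points.csv", index=False)
    manifest.outputs += ["agreement.csv", "bland_altman_points.csv"]
    manifest.counts["agreement_rows"] = len(agree)

    model_rows, variance_rows = [], []
    for metric, pair in _MODEL_GRID:
        table = build_model_table(daily, demographics, metric, pair)
        label = f"{metric}:{pair[0]}-{pair[1]}"
        try:
            res = fit_mixed(table)
        except ValueError:
            continue
        for _, row in res.terms.iterrows():
            model_rows.append({"model": label, **row.to_dict()})
        variance_rows.append(
            {
                "model": label,
                "sigma2": res.sigma2,
                "tau00": res.tau00,
                "icc": res.icc,
                "r2_marginal": res.r2_marginal,
                "r2_conditional": res.r2_conditional,
                "n_obs": res.n_obs,
                "n_participants": res.n_participants,
                "singular": res.singular,
            }
        )
    pd.DataFrame(model_rows).to_csv(out / "models.csv", index=False)
    pd.DataFrame(variance_rows).to_csv(out / "model_variance.csv", index=False)
    manifest.outputs += ["models.csv", "model_variance.csv"]
    manifest.counts["models_fitted"] = len(variance_rows)

    manifest.outputs += export_summary_tables(daily, demographics, agree, out)
    manifest.save(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest


def asdict_config(config: CohortConfig) -> dict:
    d = asdict(config)
    d["study_start_date"] = config.study_start_date.isoformat()
    return d


def export_summary_tables(daily, demographics, agree: pd.DataFrame, out_dir) -> list:
    """Write display-formatted descriptive and agreement tables.

    The descriptive table gives, per modality and group, the mean (SD) of
    onset/offset (clock-formatted means, SDs in minutes) and TST, from
    per-participant daily averages.
    """
    out = Path(out_dir)
    summaries = summarize_participants(daily).merge(
        demographics[["participant", "group"]], on="participant", how="inner"
    )
    summaries["coarse_group"] = summaries["group"].map(
        lambda g: "control" if g == "control" else "patients"
    )
    rows = []
    for (grp, modality), sub in summaries.groupby(["coarse_group", "modality"], sort=True):
        def fmt(col, clock):
            vals = sub[col].dropna()
            if vals.empty:
                return "—"
            mean, sd = vals.mean(), vals.std(ddof=1)
            shown = render_clock(mean) if clock else f"{mean / 60:.0f} h {mean % 60:.0f} min"
            return f"{shown} ({0 if pd.isna(sd) else sd:.0f} min)"

        rows.append(
            {
                "group": grp,
                "modality": modality,
                "n_participants": sub["participant"].nunique(),
                "onset_mean_sd": fmt("mean_onset_rel", clock=True),
                "offset_mean_sd": fmt("mean_offset_rel", clock=True),
                "tst_mean_sd": fmt("mean_tst", clock=False),
            }
        )
    pd.DataFrame(rows).to_csv(out / "table_descriptives.csv", index=False)

    disp = agree.copy()
    for col in ("mean_bias", "sd_diff", "loa_low", "loa_high", "t", "r"):
        if col in disp.columns:
            disp[col] = disp[col].map(lambda x: round_half_up(x) if pd.notna(x) else x)
    disp.to_csv(out / "table_agreement.csv", index=False)
    return ["table_descriptives.csv", "table_agreement.csv"]
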