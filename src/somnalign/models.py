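"""Linear mixed-effects analysis of day-level between-modality differences.

For each sleep metric (onset, offset, TST) and modality pair, the
day-level absolute difference between the two modalities (in hours) is
modeled with a random-intercept linear mixed model:

    |diff|_ij = β0 + β_age·age_i + β_sex·female_i + β_meq·MEQ_i
                + β_day·daylight_j + β_group·group_i + u_i + ε_ij,
    u_i ~ N(0, τ00),  ε_ij ~ N(0, σ²)

fitted by REML with participant random intercepts (the repeated-measures
structure of multi-night cohorts), Wald CIs/p-values, and the derived summaries

* ICC = τ00 / (τ00 + σ²)  — share of variance between participants;
* marginal R² = var(Xβ) / (var(Xβ) + τ00 + σ²) and
  conditional R² = (var(Xβ) + τ00) / (var(Xβ) + τ00 + σ²)
  (the Nakagawa & Schielzeth definitions for Gaussian models).

Daylight (sunrise-to-sunset duration for the study day at the study
site) is the seasonal covariate and is entered per hour by default; a
per-minute coefficient of the printed magnitude would be physically
implausible, so the scale is explicit and switchable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .solar import day_length

__all__ = [
    "ModelResult",
    "build_model_table",
    "fit_mixed",
    "icc",
    "r2_nakagawa",
]

MODEL_FORMULA = (
    "abs_diff ~ age + C(sex, Treatment('male')) + meq + daylight"
    " + C(group, Treatment('control'))"
)

_TERM_LABELS = {
    "Intercept": "intercept",
    "age": "age",
    "C(sex, Treatment('male'))[T.female]": "sex_female",
    "meq": "meq",
    "daylight": "daylight",
    "C(group, Treatment('control'))[T.BD]": "group_BD",
    "C(group, Treatment('control'))[T.BPD]": "group_BPD",
    "C(group, Treatment('control'))[T.MDD]": "group_MDD",
}


@dataclass
class ModelResult:
    """Fitted random-intercept model summary."""

    terms: pd.DataFrame  # term, estimate, ci_low, ci_high, p
    sigma2: float  # residual variance
    tau00: float  # participant intercept variance
    icc: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_participants: int
    singular: bool = False

    def term(self, name: str) -> pd.Series:
        """Row for one fixed-effect term (e.g. ``"age"``)."""
        return self.terms.set_index("term").loc[name]


def build_model_table(
    daily: pd.DataFrame,
    demographics: pd.DataFrame,
    metric: str,
    pair: tuple[str, str],
    *,
    latitude: float = 60.17,
    longitude: float = 24.94,
    daylight_scale: str = "hours",
) -> pd.DataFrame:
    """Day-level model table for one metric and modality pair.

    Inner-joins the two modalities on (participant, study_day), takes the
    absolute difference in hours, attaches demographics and the study
    day's daylight duration.  Days present in only one modality are
    excluded.
    """
    col = {"onset": "onset_rel_min", "offset": "offset_rel_min", "tst": "tst_min"}[metric]
    a_mod, b_mod = pair
    wide = daily.pivot_table(
        index=["participant", "study_day"], columns="modality", values=col, aggfunc="first"
    )
    if a_mod not in wide.columns or b_mod not in wide.columns:
        return pd.DataFrame(
            columns=["participant", "study_day", "abs_diff", "age", "sex", "meq", "daylight", "group"]
        )
    sub = wide[[a_mod, b_mod]].dropna().reset_index()
    sub["abs_diff"] = (sub[a_mod] - sub[b_mod]).abs() / 60.0  # minutes -> hours
    sub = sub.merge(demographics, on="participant", how="inner")
    unique_days = {d: day_length(d, latitude, longitude) for d in sub["study_day"].unique()}
    daylight_min = sub["study_day"].map(unique_days)
    sub["daylight"] = daylight_min / 60.0 if daylight_scale == "hours" else daylight_min
    return sub[
        ["participant", "study_day", "abs_diff", "age", "sex", "meq", "daylight", "group"]
    ]


def icc(sigma2: float, tau00: float) -> float:
    """Intraclass correlation τ00 / (τ00 + σ²)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if tau00 < 0:
        raise ValueError("tau00 must be >= 0")
    return tau00 / (tau00 + sigma2)


def fit_mixed(table: pd.DataFrame, formula: str = MODEL_FORMULA) -> ModelResult:
    """Fit the random-intercept model by REML and summarize it.

    A boundary fit (τ00 → 0) is returned with ``singular=True`` rather
    than raised.  Groups absent from the table simply drop their term.
    """
    counts = table.groupby("participant").size()
    if len(counts) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 participants with >= 2 observations each")
    # drop treatment levels with no data so patsy does not error
    f = formula
    present = set(table["group"].unique())
    if present == {"control"} or "group" not in table.columns:
        f = f.replace(" + C(group, Treatment('control'))", "")
    if table["sex"].nunique() < 2:
        f = f.replace(" + C(sex, Treatment('male'))", "")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f, data=table, groups=table["participant"])
        fit = model.fit(reml=True)
    sigma2 = float(fit.scale)
    tau00 = float(np.asarray(fit.cov_re)[0, 0])
    singular = tau00 < 1e-8 * max(sigma2, 1.0) or not fit.converged

    ci = fit.conf_int()
    rows = []
    for name in fit.fe_params.index:
        rows.append(
            {
                "term": _TERM_LABELS.get(name, name),
                "estimate": float(fit.fe_params[name]),
                "ci_low": float(ci.loc[name, 0]),
                "ci_high": float(ci.loc[name, 1]),
                "p": float(fit.pvalues[name]),
            }
        )
    terms = pd.DataFrame(rows)

    fixed_pred = np.asarray(model.exog) @ np.asarray(fit.fe_params)
    r2m, r2c = r2_nakagawa(fixed_pred, sigma2, tau00)
    return ModelResult(
        terms=terms,
        sigma2=sigma2,
        tau00=tau00,
        icc=icc(sigma2, tau00),
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=len(table),
        n_participants=table["participant"].nunique(),
        singular=singular,
    )


def r2_nakagawa(fixed_predictions, sigma2: float, tau00: float) -> tuple[float, float]:
    """Marginal and conditional R² from the fitted variance budget.

    ``var_f`` is the variance of the fixed-effect linear predictor; the
    marginal R² is var_f over the total (var_f + τ00 + σ²) and the
    conditional R² adds τ00 to the numerator.
    """
    var_f = float(np.var(np.asarray(fixed_predictions, dtype=float), ddof=1))
    total = var_f + tau00 + sigma2
    return var_f / total, (var_f + tau00) / total
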