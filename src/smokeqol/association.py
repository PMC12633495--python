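"""Adjusted linear association models, effect modification and sensitivity.

Each model regresses one HRQoL outcome on one windowed exposure metric with
the study's adjustment set: SGRQ outcomes adjust for age, sex, ethnicity,
BMI, education, current smoking, pack-years and airway obstruction; SF-36
outcomes swap airway obstruction for baseline comorbidity.  Nominal two-sided
P values are reported with no multiple-testing correction; evidence is meant
to be weighed across metrics and windows rather than dichotomized.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ADJUST_SGRQ",
    "ADJUST_SF36",
    "ModelResult",
    "InteractionResult",
    "adjustment_for",
    "rescale_exposure",
    "fit_main",
    "fit_interaction",
    "sensitivity_winter",
    "run_full_grid",
    "render_wide",
    "EXPOSURE_UNITS",
]

ADJUST_SGRQ = ("age", "female", "hispanic", "bmi", "some_college",
               "current_smoker", "pack_years", "airway_obstruction")
ADJUST_SF36 = ("age", "female", "hispanic", "bmi", "some_college",
               "current_smoker", "pack_years", "comorbidity")

INTERACTION_MODIFIERS = ("female", "some_college", "current_smoker",
                         "woodsmoke_ever", "cmh", "hispanic")

# primary reporting unit per exposure metric
EXPOSURE_UNITS = {
    "total_pm25": ("per 1 μg/m³", 1.0),
    "smoke_pm25": ("per 1 μg/m³", 1.0),
    "smoke_bc": ("per 0.05 μg/m³", 0.05),
    "n_smoke_days": ("per 1 day", 1.0),
    "cum_area": ("per IQR", "iqr"),
}


def adjustment_for(outcome: str) -> tuple[str, ...]:
    return ADJUST_SGRQ if outcome.startswith("sgrq") else ADJUST_SF36


@dataclass
class ModelResult:
    outcome: str
    exposure: str
    unit: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_dropped: int
    r2: float
    resid_sd: float
    scale: float = 1.0  # multiplicative unit scale applied to the raw metric


@dataclass
class InteractionResult:
    modifier: str
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    slope_stratum0: float
    slope_stratum1: float
    meaningful: bool = field(init=False)

    def __post_init__(self) -> None:
        self.meaningful = self.p_interaction < 0.1


def rescale_exposure(values: pd.Series, unit: str | float) -> tuple[pd.Series, str, float]:
    """Express an exposure metric in the reporting unit.

    A coefficient per `u` units of x is the coefficient of x/u, so
    β(per 0.05) = 0.05 × β(per 1) exactly.  ``unit`` is a numeric unit size,
    or 'iqr' to use the analysis sample's IQR of the non-missing values.
    """
    if isinstance(unit, str) and unit.lower() == "iqr":
        u = float(stats.iqr(values.dropna()))
        if u == 0:
            raise ValueError("IQR of the exposure is zero; per-IQR scaling undefined")
        label = f"per IQR ({u:.4g})"
    else:
        u = float(unit)
        if u <= 0:
            raise ValueError("unit size must be positive")
        label = f"per {u:g}"
    return values / u, label, u


def _design(rows: pd.DataFrame, outcome: str, exposure_col: str,
            adjustment: tuple[str, ...]) -> tuple[pd.DataFrame, pd.Series, int]:
    cols = [outcome, exposure_col, *adjustment]
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise ValueError(f"analysis table lacks columns: {missing}")
    sub = rows.loc[:, cols].dropna()
    n_dropped = len(rows) - len(sub)
    X = sm.add_constant(sub[[exposure_col, *adjustment]].astype(float), has_constant="add")
    return X, sub[outcome].astype(float), n_dropped


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        bad = []
        for j, col in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_main(
    rows: pd.DataFrame,
    outcome: str,
    exposure_col: str,
    unit: str | float = 1.0,
    adjustment: tuple[str, ...] | None = None,
) -> ModelResult:
    """OLS of one outcome on one scaled exposure metric plus the adjustment set."""
    adjustment = adjustment if adjustment is not None else adjustment_for(outcome)
    scaled, label, u = rescale_exposure(rows[exposure_col], unit)
    rows = rows.assign(**{exposure_col: scaled})
    X, y, n_dropped = _design(rows, outcome, exposure_col, adjustment)
    if len(y) < X.shape[1] + 20:
        raise ValueError(f"only {len(y)} complete rows for {X.shape[1]} parameters")
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc[exposure_col]
    return ModelResult(
        outcome=outcome, exposure=exposure_col, unit=label,
        beta=float(fit.params[exposure_col]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p=float(fit.pvalues[exposure_col]),
        n=int(fit.nobs), n_dropped=n_dropped,
        r2=float(fit.rsquared), resid_sd=float(np.sqrt(fit.mse_resid)),
        scale=u,
    )


def fit_interaction(
    rows: pd.DataFrame,
    outcome: str,
    exposure_col: str,
    modifier: str,
    unit: str | float = 1.0,
    adjustment: tuple[str, ...] | None = None,
) -> InteractionResult:
    """Main model plus a modifier × exposure product term.

    The modifier must be binary 0/1 with both strata present; the stratum
    slopes are β (stratum 0) and β + γ (stratum 1).  Interactions are, by the
    study design, examined for the 7-day metrics where associations are
    strongest.
    """
    adjustment = adjustment if adjustment is not None else adjustment_for(outcome)
    scaled, _, _ = rescale_exposure(rows[exposure_col], unit)
    rows = rows.assign(**{exposure_col: scaled})
    if modifier not in rows.columns:
        raise ValueError(f"modifier {modifier!r} not in analysis table")
    levels = set(pd.unique(rows[modifier].dropna()))
    if not levels <= {0, 1} or len(levels) < 2:
        raise ValueError(f"modifier {modifier!r} must be binary 0/1 with both strata present")
    adj = tuple(a for a in adjustment if a != modifier) + (modifier,)
    inter = f"{exposure_col}:{modifier}"
    rows = rows.assign(**{inter: rows[exposure_col] * rows[modifier]})
    X, y, _ = _design(rows, outcome, exposure_col, adj + (inter,))
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    b = fit.params
    return InteractionResult(
        modifier=modifier,
        beta_interaction=float(b[inter]),
        se_interaction=float(fit.bse[inter]),
        p_interaction=float(fit.pvalues[inter]),
        slope_stratum0=float(b[exposure_col]),
        slope_stratum1=float(b[exposure_col] + b[inter]),
    )


def sensitivity_winter(
    rows: pd.DataFrame,
    winter_months: tuple[int, ...] = (12, 1, 2),
) -> tuple[pd.DataFrame, int]:
    """Drop visits made in winter months; returns (filtered rows, n excluded).

    Smoke events are rare in the cold season, so exclusion probes whether the
    associations are carried by the fire season.
    """
    if "visit_date" not in rows.columns:
        raise ValueError("visit_date column required")
    months = pd.to_datetime(rows["visit_date"]).dt.month
    keep = ~months.isin(winter_months)
    if not keep.any():
        raise ValueError("winter exclusion removed every row")
    return rows.loc[keep].copy(), int((~keep).sum())


_GRID_OUTCOMES = ("sgrq_activity", "sgrq_impacts", "sgrq_symptom", "sgrq_total",
                  "sf36_mental", "sf36_physical")
_GRID_EXPOSURES = ("total_pm25", "smoke_pm25", "smoke_bc", "n_smoke_days", "cum_area")


def run_full_grid(
    rows: pd.DataFrame,
    outcomes=_GRID_OUTCOMES,
    exposures=_GRID_EXPOSURES,
    windows=(7, 15, 30, 60),
) -> pd.DataFrame:
    """Fit the full outcome × exposure-metric × window grid.

    One tidy row per combination at its primary reporting unit; smoke PM2.5
    rows additionally carry the per-0.05 μg/m³ rescaling (an exact
    reparameterization).  A failed single model records its error in the
    ``error`` column rather than aborting the grid.
    """
    records = []
    for outcome, metric, x in itertools.product(outcomes, exposures, windows):
        col = f"{metric}_{x}d"
        rec = {"outcome": outcome, "metric": metric, "window": x, "exposure": col}
        try:
            unit = EXPOSURE_UNITS[metric][1]
            res = fit_main(rows, outcome, col, unit=unit)
            rec.update(unit=res.unit, beta=res.beta, ci_low=res.ci_low,
                       ci_high=res.ci_high, p=res.p, n=res.n, error="")
            if metric == "smoke_pm25":
                rec.update(beta_per005=0.05 * res.beta,
                           ci_low_per005=0.05 * res.ci_low,
                           ci_high_per005=0.05 * res.ci_high)
        except Exception as exc:  # recorded, not fatal
            rec.update(unit="", beta=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p=np.nan, n=0, error=str(exc))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def render_wide(grid: pd.DataFrame, outcomes=None) -> str:
    """Markdown rendering of the grid: rows = exposure × window, columns =
    outcomes, cells = 'β (lo, hi) / p'."""
    outcomes = outcomes if outcomes is not None else list(dict.fromkeys(grid["outcome"]))
    lines = ["| Exposure | " + " | ".join(outcomes) + " |",
             "|---" * (len(outcomes) + 1) + "|"]
    for (metric, x), sub in grid.groupby(["metric", "window"], sort=False):
        unit = sub["unit"].iloc[0]
        cells = []
        for o in outcomes:
            r = sub[sub["outcome"] == o]
            if len(r) == 0 or r["error"].iloc[0]:
                cells.append("—")
            else:
                r = r.iloc[0]
                cells.append(f"{r.beta:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f}), p={r.p:.2g}")
        lines.append(f"| {metric} {x}d ({unit}) | " + " | ".join(cells) + " |")
    return "\n".join(lines)
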