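"""Synthetic cohort, plume-calendar, pollutant-field and outcome generator.

The generator emulates the study system end to end with known ground truth:

* a seasonal smoke-day calendar with plume polygons over a desert-Southwest
  style catchment (smoke concentrated in late spring/summer, rare in winter);
* daily 1×1 km total PM2.5 / black-carbon fields = multiplicative lognormal
  baseline + additive smoke elevation on smoke days only, with the planted
  additive term recorded per cell-day;
* a smoker cohort with the study's covariate marginals (n = 747 by default);
* HRQoL outcomes from a linear model with planted exposure effects and
  Gaussian noise, clamped to the instruments' score ranges.

Every stage is a pure function of a :class:`SimulationConfig` and a seed, so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Point

from .geometry import PlumeRecord, StudyArea, default_study_area, detect_smoke_days

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gen_smoke_calendar",
    "gen_cohort",
    "gen_pollutant_fields",
    "gen_outcomes",
    "make_grid_cells",
    "SGRQ_OUTCOMES",
    "SF36_FACTOR_OUTCOMES",
]

SGRQ_OUTCOMES = ("sgrq_activity", "sgrq_impacts", "sgrq_symptom", "sgrq_total")
SF36_FACTOR_OUTCOMES = ("sf36_mental", "sf36_physical")

# Per-day smoke probability by calendar month: fire season peaks May-August,
# winter smoke events essentially absent.  Weighted mean ≈ 0.11, matching a
# 474-smoke-day / 4383-day record.
_DEFAULT_SEASON = {
    1: 0.01, 2: 0.01, 3: 0.05, 4: 0.10, 5: 0.20, 6: 0.32,
    7: 0.28, 8: 0.20, 9: 0.10, 10: 0.05, 11: 0.02, 12: 0.01,
}

# Baseline medians are calibrated so that with the default lognormal noise
# (sigma = 0.5) the *mean* non-smoke-day concentration is 4.14 μg/m³ PM2.5 and
# 0.16 μg/m³ BC: median = mean · exp(-sigma²/2).  Smoke elevations are the
# observed smoke-day minus non-smoke-day mean differences (6.55-4.14 and
# 0.25-0.16).
_BASELINE_SIGMA = 0.5
_PM25_NONSMOKE_MEAN = 4.14
_BC_NONSMOKE_MEAN = 0.16

# Covariate marginals of the cohort (proportions / moments).
_DEFAULT_COVARIATES = {
    "age": {"dist": "truncnorm", "mean": 56.87, "sd": 9.08, "lo": 40.0, "hi": 75.0},
    "female": {"dist": "bernoulli", "p": 0.5127},
    "bmi": {"dist": "truncnorm", "mean": 28.78, "sd": 6.35, "lo": 15.0, "hi": 60.0},
    "hispanic": {"dist": "bernoulli", "p": 0.2477},
    "some_college": {"dist": "bernoulli", "p": 0.6412},
    "current_smoker": {"dist": "bernoulli", "p": 0.5984},
    "pack_years": {"dist": "truncnorm", "mean": 41.41, "sd": 20.96, "lo": 10.0, "hi": 150.0},
    "woodsmoke_ever": {"dist": "bernoulli", "p": 0.3226},
    "cmh": {"dist": "bernoulli", "p": 0.3066},
    "pulmonary_disease": {"dist": "bernoulli", "p": 0.1339},
    # not tabulated in the cohort description; plausible values for a
    # >=10-pack-year smoker cohort
    "airway_obstruction": {"dist": "bernoulli", "p": 0.35},
    "comorbidity": {"dist": "bernoulli", "p": 0.50},
}

# Planted exposure effects: the 7-day smoke-PM2.5 coefficients used as ground
# truth for recovery experiments (per 1 μg/m³ of 7-day mean smoke PM2.5).
_DEFAULT_BETAS = {
    ("sgrq_activity", "smoke_pm25", 7): 5.51,
    ("sgrq_impacts", "smoke_pm25", 7): 3.27,
    ("sgrq_symptom", "smoke_pm25", 7): 6.15,
    ("sgrq_total", "smoke_pm25", 7): 4.68,
    ("sf36_mental", "smoke_pm25", 7): -0.172,
    ("sf36_physical", "smoke_pm25", 7): -0.214,
}

# Residual noise SDs (score points; SD units for the standardized factors) and
# intercepts.  Intercepts sit mid-range so that [0,100] clamping stays rare
# (~1-2%): boundary censoring attenuates planted slopes, so a well-posed
# recovery design keeps it minimal.
_DEFAULT_NOISE_SD = {
    "sgrq_activity": 24.0, "sgrq_impacts": 14.0, "sgrq_symptom": 20.0,
    "sgrq_total": 16.0, "sf36_mental": 0.90, "sf36_physical": 0.88,
}
_DEFAULT_INTERCEPTS = {
    "sgrq_activity": 48.0, "sgrq_impacts": 28.0, "sgrq_symptom": 45.0,
    "sgrq_total": 38.0, "sf36_mental": 0.0, "sf36_physical": 0.0,
}
# Modest covariate effects; continuous covariates enter centred at their
# configured means so intercepts stay interpretable as population means.
_DEFAULT_COV_EFFECTS = {
    "sgrq": {"age": 0.08, "female": -1.0, "bmi": 0.12, "hispanic": 0.8,
             "some_college": -2.0, "current_smoker": 3.0, "pack_years": 0.05,
             "airway_obstruction": 6.0, "cmh": 3.0},
    "sf36": {"age": -0.008, "female": 0.05, "bmi": -0.01, "hispanic": -0.05,
             "some_college": 0.10, "current_smoker": -0.15, "pack_years": -0.003,
             "comorbidity": -0.40},
}

# Fixed simple-structure loadings used when emitting SF-36 domain scores from
# the two latent factors (physical set, then mental set).
SF36_DOMAIN_LOADINGS = {
    "physical_functioning": ("physical", 0.85),
    "role_physical": ("physical", 0.80),
    "bodily_pain": ("physical", 0.70),
    "general_health": ("physical", 0.75),
    "mental_health": ("mental", 0.85),
    "role_emotional": ("mental", 0.75),
    "social_functioning": ("mental", 0.70),
    "vitality": ("mental", 0.65),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults set to the study
    conditions the generator emulates."""

    seed: int = 0
    n_cells: int = 25
    date_range: tuple[str, str] = ("2009-01-01", "2014-12-31")
    smoke_season_prob: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_SEASON))
    baseline_pm25_median: float = _PM25_NONSMOKE_MEAN * math.exp(-_BASELINE_SIGMA ** 2 / 2)
    baseline_bc_median: float = _BC_NONSMOKE_MEAN * math.exp(-_BASELINE_SIGMA ** 2 / 2)
    baseline_log_sd: float = _BASELINE_SIGMA
    smoke_elevation_pm25_mean: float = 6.55 - _PM25_NONSMOKE_MEAN
    smoke_elevation_bc_mean: float = 0.25 - _BC_NONSMOKE_MEAN
    smoke_spatial_sd: float = 0.15  # lognormal SD of the per-cell elevation factor
    n_subjects: int = 747
    noise_sd_outcome: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    intercepts: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_INTERCEPTS))
    planted_betas: Mapping[tuple[str, str, int], float] = field(
        default_factory=lambda: dict(_DEFAULT_BETAS))
    covariate_dists: Mapping[str, Mapping] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COVARIATES.items()})
    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COV_EFFECTS.items()})
    clamp_warn_rate: float = 0.05

    def __post_init__(self) -> None:
        start, end = (_dt.date.fromisoformat(d) for d in self.date_range)
        if end < start:
            raise ValueError("date_range end precedes start")
        # the deviation baseline pools the same calendar month over the year
        # before and the year after, so the record must span >= 3 years
        n_years = end.year - start.year + 1
        if n_years < 3:
            raise ValueError(
                "date_range must span at least 3 calendar years: the smoke "
                "attribution baseline pools non-smoke days from the year "
                "before and the year after each smoke day")
        for m, p in self.smoke_season_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"smoke probability for month {m} outside [0, 1]")
        for name in ("baseline_pm25_median", "baseline_bc_median"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.smoke_elevation_pm25_mean < 0 or self.smoke_elevation_bc_mean < 0:
            raise ValueError("smoke elevations must be non-negative")

    @property
    def start(self) -> _dt.date:
        return _dt.date.fromisoformat(self.date_range[0])

    @property
    def end(self) -> _dt.date:
        return _dt.date.fromisoformat(self.date_range[1])


@dataclass
class GroundTruth:
    """Planted truth stored alongside every simulated dataset."""

    smoke_days: pd.DatetimeIndex
    contributions: pd.DataFrame  # cell_id, date, baseline/planted pm25 & bc
    planted_betas: dict
    pre_clamp: pd.DataFrame | None = None
    clamp_counts: dict | None = None


def _day_index(config: SimulationConfig) -> pd.DatetimeIndex:
    return pd.date_range(config.start, config.end, freq="D", name="date")


def gen_smoke_calendar(
    config: SimulationConfig,
    area: StudyArea | None = None,
    threshold_km2: float = 1.0,
) -> tuple[pd.DataFrame, list[PlumeRecord]]:
    """Draw a seasonal smoke-day calendar and consistent plume polygons.

    Each smoke day gets one plume disk that overlaps the study area by at
    least the detection threshold; a fraction of non-smoke days carry decoy
    plumes far outside the study area.  The returned table is produced by
    running :func:`detect_smoke_days` on the generated plumes, so calendar and
    geometry agree by construction.
    """
    area = area if area is not None else default_study_area()
    rng = np.random.default_rng(config.seed)
    days = _day_index(config)
    probs = np.array([config.smoke_season_prob.get(m, 0.0) for m in days.month])
    is_smoke_planned = rng.random(len(days)) < probs

    cx, cy = 0.0, 0.0  # study centroid in its own projected plane
    plumes: list[PlumeRecord] = []
    for day, smoke in zip(days, is_smoke_planned):
        if smoke:
            # disk roughly over the catchment; guaranteed >= threshold overlap
            ox, oy = rng.normal(0.0, 40.0, size=2)
            radius = rng.uniform(20.0, 120.0)
            disk = Point(cx + ox, cy + oy).buffer(radius, quad_segs=24)
            if disk.intersection(area.projected).area < threshold_km2:
                disk = Point(cx, cy).buffer(radius, quad_segs=24)
            plumes.append(PlumeRecord(date=day.date(), geometry=area.projection.unproject(disk)))
        elif rng.random() < 0.10:
            # decoy plume well away from the catchment
            angle = rng.uniform(0, 2 * np.pi)
            ox, oy = 600.0 * np.cos(angle), 600.0 * np.sin(angle)
            disk = Point(ox, oy).buffer(rng.uniform(20.0, 80.0), quad_segs=16)
            plumes.append(PlumeRecord(date=day.date(), geometry=area.projection.unproject(disk)))

    table = detect_smoke_days(plumes, area, config.start, config.end, threshold_km2)
    if not np.array_equal(table["is_smoke"].to_numpy(), is_smoke_planned):
        raise AssertionError("generated plumes disagree with the planned calendar")
    return table, plumes


def make_grid_cells(config: SimulationConfig, area: StudyArea | None = None) -> pd.DataFrame:
    """Centers of n_cells 1×1 km grid cells around the study-area centroid."""
    area = area if area is not None else default_study_area()
    k = math.ceil(math.sqrt(config.n_cells))
    offs = (np.arange(k) - (k - 1) / 2.0) * 1.0  # 1 km spacing
    xx, yy = np.meshgrid(offs, offs)
    pts = np.column_stack([xx.ravel(), yy.ravel()])[: config.n_cells]
    lonlat = area.projection.inverse(pts)
    return pd.DataFrame({
        "cell_id": np.arange(config.n_cells),
        "lon": lonlat[:, 0],
        "lat": lonlat[:, 1],
    })


def gen_pollutant_fields(
    config: SimulationConfig,
    calendar: pd.DataFrame,
    cells: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate daily total PM2.5 / BC per grid cell with planted smoke terms.

    total = lognormal baseline (median = configured median, month-stationary)
    + additive smoke elevation on smoke days only.  The per-day regional
    elevation is exponential with the configured mean; per-cell factors are
    lognormal with mean 1 and SD ``smoke_spatial_sd``.  BC shares the day/cell
    smoke structure through the configured BC:PM2.5 elevation ratio.
    """
    cells = cells if cells is not None else make_grid_cells(config)
    days = calendar.index
    if not days.equals(_day_index(config)):
        raise ValueError("calendar does not cover the configured date_range")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_days, n_cells = len(days), len(cells)
    sigma = config.baseline_log_sd

    base_pm = rng.lognormal(math.log(config.baseline_pm25_median), sigma, (n_days, n_cells))
    base_bc = rng.lognormal(math.log(config.baseline_bc_median), sigma, (n_days, n_cells))

    smoke = calendar["is_smoke"].to_numpy()
    elev_day = np.zeros(n_days)
    elev_day[smoke] = rng.exponential(config.smoke_elevation_pm25_mean, smoke.sum())
    s = config.smoke_spatial_sd
    if s > 0:
        factors = rng.lognormal(-0.5 * math.log(1 + s ** 2), math.sqrt(math.log(1 + s ** 2)),
                                (n_days, n_cells))
    else:
        factors = np.ones((n_days, n_cells))
    planted_pm = elev_day[:, None] * factors
    planted_pm[~smoke, :] = 0.0
    bc_ratio = config.smoke_elevation_bc_mean / config.smoke_elevation_pm25_mean \
        if config.smoke_elevation_pm25_mean > 0 else 0.0
    planted_bc = planted_pm * bc_ratio

    long = pd.DataFrame({
        "cell_id": np.tile(cells["cell_id"].to_numpy(), n_days),
        "lon": np.tile(cells["lon"].to_numpy(), n_days),
        "lat": np.tile(cells["lat"].to_numpy(), n_days),
        "date": np.repeat(days.to_numpy(), n_cells),
        "pm25": (base_pm + planted_pm).ravel(),
        "bc": (base_bc + planted_bc).ravel(),
    })
    truth = GroundTruth(
        smoke_days=days[smoke],
        contributions=pd.DataFrame({
            "cell_id": long["cell_id"],
            "date": long["date"],
            "baseline_pm25": base_pm.ravel(),
            "baseline_bc": base_bc.ravel(),
            "planted_pm25": planted_pm.ravel(),
            "planted_bc": planted_bc.ravel(),
        }),
        planted_betas=dict(config.planted_betas),
    )
    return long, truth


def _sample_covariate(rng: np.random.Generator, spec: Mapping, n: int) -> np.ndarray:
    if spec["dist"] == "bernoulli":
        return (rng.random(n) < spec["p"]).astype(int)
    if spec["dist"] == "truncnorm":
        a = (spec["lo"] - spec["mean"]) / spec["sd"]
        b = (spec["hi"] - spec["mean"]) / spec["sd"]
        return stats.truncnorm.rvs(a, b, loc=spec["mean"], scale=spec["sd"], size=n,
                                   random_state=rng)
    raise ValueError(f"unknown covariate distribution {spec['dist']!r}")


def gen_cohort(
    config: SimulationConfig,
    area: StudyArea | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a baseline-visit cohort with the configured covariate marginals.

    Visit dates are uniform over the interior of the simulated record (one
    full year plus the longest exposure window trimmed from the start, one
    year from the end) so every visit has complete window coverage and a
    fully pooled attribution baseline.  Residences are uniform points inside
    the study area.
    """
    n = config.n_subjects
    n_adjust = 8  # size of the larger adjustment set
    if n <= n_adjust:
        raise ValueError(
            f"n_subjects={n} does not exceed the {n_adjust} adjustment covariates; "
            "downstream models would be unidentifiable")
    area = area if area is not None else default_study_area()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2] if seed is None else [config.seed, 2, seed]))

    cov = {name: _sample_covariate(rng, spec, n)
           for name, spec in config.covariate_dists.items()}

    first = pd.Timestamp(config.start) + pd.Timedelta(days=366 + 60)
    last = pd.Timestamp(config.end) - pd.Timedelta(days=366)
    if last < first:
        raise ValueError("date_range too short to place visits with full coverage")
    offsets = rng.integers(0, (last - first).days + 1, size=n)
    visit_dates = first + pd.to_timedelta(offsets, unit="D")

    # uniform residence points inside the catchment polygon
    minx, miny, maxx, maxy = area.projected.bounds
    pts = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = np.column_stack([
            rng.uniform(minx, maxx, size=2 * n),
            rng.uniform(miny, maxy, size=2 * n),
        ])
        inside = shapely.contains_xy(area.projected, cand[:, 0], cand[:, 1])
        keep = cand[inside][: n - filled]
        pts[filled: filled + len(keep)] = keep
        filled += len(keep)
    lonlat = area.projection.inverse(pts)

    return pd.DataFrame({
        "subject_id": np.arange(n),
        "visit_date": visit_dates,
        "lon": lonlat[:, 0],
        "lat": lonlat[:, 1],
        **cov,
    })


def gen_outcomes(
    visits: pd.DataFrame,
    exposures: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
    emit_domains: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate HRQoL outcome scores from the planted linear model.

    outcome = intercept + covariate effects + Σ planted β × exposure metric
    + Gaussian noise; SGRQ scores are then clamped to [0, 100] (clamp events
    counted, pre-clamp values kept in the returned ground truth).  SF-36
    mental/physical factor outcomes are generated directly on the
    standardized factor-score scale and are not clamped.  With
    ``emit_domains`` the eight SF-36 domain scores are also emitted from the
    two latent factors under a fixed simple structure.
    """
    if len(visits) == 0:
        raise ValueError("empty cohort: no visits to score")
    for (outcome, metric, window), beta in config.planted_betas.items():
        col = f"{metric}_{window}d"
        if col not in exposures.columns:
            raise ValueError(f"planted beta for {outcome} references missing exposure column {col!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 3] if seed is None else [config.seed, 3, seed]))

    n = len(visits)
    means = {name: spec.get("mean", spec.get("p", 0.0))
             for name, spec in config.covariate_dists.items()}

    def covariate_term(group: str) -> np.ndarray:
        total = np.zeros(n)
        for name, eff in config.covariate_effects[group].items():
            x = visits[name].to_numpy(dtype=float)
            if config.covariate_dists[name]["dist"] == "truncnorm":
                x = x - means[name]
            total += eff * x
        return total

    raw = {}
    for outcome in SGRQ_OUTCOMES + SF36_FACTOR_OUTCOMES:
        group = "sgrq" if outcome.startswith("sgrq") else "sf36"
        y = np.full(n, config.intercepts[outcome]) + covariate_term(group)
        for (out, metric, window), beta in config.planted_betas.items():
            if out == outcome:
                y = y + beta * exposures[f"{metric}_{window}d"].to_numpy()
        y = y + rng.normal(0.0, config.noise_sd_outcome[outcome], n)
        raw[outcome] = y

    scores = pd.DataFrame({"subject_id": visits["subject_id"].to_numpy()})
    clamp_counts = {}
    for outcome in SGRQ_OUTCOMES:
        y = raw[outcome]
        clamped = np.clip(y, 0.0, 100.0)
        n_clamped = int((clamped != y).sum())
        clamp_counts[outcome] = n_clamped
        if n_clamped > config.clamp_warn_rate * n:
            warnings.warn(
                f"{outcome}: {n_clamped}/{n} scores clamped to [0, 100] "
                f"(> {config.clamp_warn_rate:.0%}); planted slopes will attenuate",
                stacklevel=2)
        scores[outcome] = clamped
    for outcome in SF36_FACTOR_OUTCOMES:
        scores[outcome] = raw[outcome]

    if emit_domains:
        latent = {"physical": raw["sf36_physical"], "mental": raw["sf36_mental"]}
        for dom, (fac, lam) in SF36_DOMAIN_LOADINGS.items():
            z = lam * latent[fac] + math.sqrt(1 - lam ** 2) * rng.normal(0.0, 1.0, n)
            scores[dom] = np.clip(55.0 + 18.0 * z, 0.0, 100.0)

    truth = GroundTruth(
        smoke_days=pd.DatetimeIndex([]),
        contributions=pd.DataFrame(),
        planted_betas=dict(config.planted_betas),
        pre_clamp=pd.DataFrame(raw).assign(subject_id=visits["subject_id"].to_numpy()),
        clamp_counts=clamp_counts,
    )
    return scores, truth
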