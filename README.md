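# smokeqol

Wildfire-smoke exposure attribution and its linkage to health-related
quality of life (HRQoL), built for epidemiologists studying episodic smoke
exposure in downwind cohorts.

Wildfire smoke that has travelled 150–200 miles still degrades near-ground
air quality in an episodic way. This package implements the full analysis
chain for relating such episodes to respiratory-specific (SGRQ) and generic
(SF-36) quality-of-life measures in a cohort of smokers:

1. **Smoke-day detection** — a calendar day is a *smoke day* when
   satellite-detected plume polygons overlap the study catchment by at least
   1 km² (union over the day's plumes, equal-area projection).
2. **Smoke attribution (deviation method)** — for a smoke day *t* in month
   *m* of year *y*, with observed concentration *C<sub>t</sub>*,

   smoke *C<sub>t</sub>* = max(0, *C<sub>t</sub>* − median{*C<sub>s</sub>* :
   *s* a non-smoke day in month *m* of years *y−1, y, y+1*}),

   applied identically to total PM₂.₅ and black carbon (BC); non-smoke days
   are attributed 0.
3. **Exposure windows** — per subject visit, means of smoke PM₂.₅/BC and
   total PM₂.₅, the smoke-day count, and the cumulative overlapped area over
   the 7, 15, 30 and 60 days preceding the questionnaire.
4. **HRQoL scoring** — SGRQ (0–100, higher = worse; weights supplied by the
   user, as the official table is licensed) and SF-36 (eight 0–100 domains,
   higher = better) reduced to standardized physical/mental factor scores by
   a fixed-structure two-correlated-factor ML model.
5. **Association models** — OLS of each outcome on each scaled exposure
   metric (per 1 μg/m³, per 0.05 μg/m³, per day, per IQR) with the study
   adjustment sets (age, sex, ethnicity, BMI, education, current smoking,
   pack-years, plus airway obstruction for SGRQ / comorbidity for SF-36),
   product-term interaction analyses (meaningful at P < 0.1) and a
   winter-exclusion sensitivity analysis.

Because cohort and raster data of this kind are not freely redistributable,
the package ships a first-class synthetic generator
(`smokeqol.synthetic`) that emulates the study conditions with known ground
truth — seasonal plume calendars, lognormal-baseline pollutant fields with
additive smoke elevations, a 747-smoker cohort with realistic covariate
marginals, and outcomes from a linear model with planted exposure effects —
so every stage is testable end to end.

## Worked example

`examples/02_attribution.py` simulates a 4-year daily record and recovers
the planted smoke contribution by the deviation method:

```
            total_pm25  baseline_pm25  smoke_pm25
date
2009-01-07        8.05           3.75        4.30
2009-02-07        5.45           3.70        1.75
2009-04-01        5.17           3.74        1.43
...
smoke days: 160;  mean attributed smoke PM2.5 on smoke days: 2.14 μg/m³ (planted elevation mean: 2.41 μg/m³)
```

Each smoke day's attributed concentration is the observed regional mean
minus the pooled non-smoke-day monthly median, floored at zero; on average
it tracks the planted additive elevation (the small shortfall is the
zero-truncation of noisy days). `examples/05_association_grid.py` continues
through the full model grid:

```
fitted 120 models; failures: 0

7-day smoke PM2.5 (per 1 μg/m³), planted vs recovered:
   sgrq_activity: β =   5.66 (  2.53,   8.80), p = 0.000417 [planted 5.51]
    sgrq_impacts: β =   4.20 (  2.36,   6.03), p = 8.31e-06 [planted 3.27]
      sgrq_total: β =   5.82 (  3.70,   7.94), p = 9.67e-08 [planted 4.68]
...
woodsmoke × smoke PM2.5 interaction: β = 2.28, p = 0.32, meaningful(P<0.1) = False
winter exclusion: dropped 156 visits; sgrq_total β = 6.47 (4.29, 8.65)
```

A positive SGRQ coefficient means a 1 μg/m³ higher 7-day mean smoke PM₂.₅
is associated with that many points worse respiratory quality of life
(4 points is the instrument's minimal clinically important difference); the
single-replicate estimates scatter around the planted effects within their
CIs.

The other examples cover smoke-day geometry (`01`), window metrics and the
any-smoke-visit pattern across windows (`03`), and SGRQ/SF-36 scoring with
the factor reduction (`04`).

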