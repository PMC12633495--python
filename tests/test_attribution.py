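"""Deviation-method attribution: baselines, truncation, oracle equivalence."""

import warnings

import numpy as np
import pandas as pd
import pytest

from smokeqol import synthetic
from smokeqol.attribution import (
    attribute_day,
    attribute_grid,
    attribute_regional,
    attribute_series,
    nonsmoke_monthly_median,
    regional_mean_series,
)


def make_smokedays(index, smoke_dates):
    smoke = pd.Series(False, index=index)
    smoke.loc[list(smoke_dates)] = True
    return pd.DataFrame({"is_smoke": smoke, "overlap_km2": smoke.astype(float) * 10})


def naive_baseline(series, smokedays, target, fallback="missing"):
    """Brute-force re-derivation: enumerate qualifying days, sort, median."""
    target = pd.Timestamp(target)
    vals = []
    months = [target.month]
    for attempt in range(2):
        vals = []
        for date, v in series.items():
            if date.month in months and abs(date.year - target.year) <= 1 \
                    and not smokedays.loc[date, "is_smoke"] and not np.isnan(v):
                vals.append(v)
        if vals or fallback != "widen":
            break
        months = [(target.month % 12) + 1, ((target.month - 2) % 12) + 1]
    if not vals:
        return float("nan")
    vals = sorted(vals)
    n = len(vals)
    return vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])


class TestMonthlyMedian:
    def test_hand_median_even_count(self):
        idx = pd.date_range("2011-06-01", periods=5, freq="D")
        series = pd.Series([4.0, 4.0, 4.0, 6.0, 99.0], index=idx)
        sd = make_smokedays(idx, ["2011-06-05"])  # the 99 sits on a smoke day
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = nonsmoke_monthly_median(series, sd, "2011-06-05")
        assert got == 4.0

    def test_constant_series_returns_constant(self):
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        series = pd.Series(7.5, index=idx)
        sd = make_smokedays(idx, ["2011-06-10"])
        got = nonsmoke_monthly_median(series, sd, "2011-06-10")
        assert got == 7.5

    def test_pools_same_month_across_three_years(self):
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        series = pd.Series(0.0, index=idx)
        series[idx.year == 2010] = 10.0
        series[idx.year == 2011] = 20.0
        series[idx.year == 2012] = 30.0
        sd = make_smokedays(idx, ["2011-06-10"])
        got = nonsmoke_monthly_median(series, sd, "2011-06-10")
        assert got == 20.0  # median of 30+29+30 June days across the 3 years

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(2)
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        series = pd.Series(rng.lognormal(1.3, 0.5, len(idx)), index=idx)
        smoke_dates = idx[rng.random(len(idx)) < 0.15]
        sd = make_smokedays(idx, smoke_dates)
        for target in ["2011-06-10", "2011-01-03", "2010-02-27", "2012-12-01"]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = nonsmoke_monthly_median(series, sd, target)
            assert got == pytest.approx(naive_baseline(series, sd, target), abs=1e-12)

    def test_boundary_years_pool_available_and_warn(self):
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        series = pd.Series(5.0, index=idx)
        sd = make_smokedays(idx, ["2010-06-10"])  # no year-before in the record
        with pytest.warns(UserWarning, match="fewer than 3 years"):
            got = nonsmoke_monthly_median(series, sd, "2010-06-10")
        assert got == 5.0

    def test_no_qualifying_days_widen_vs_missing(self):
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        series = pd.Series(3.0, index=idx)
        series[idx.month == 5] = 1.0
        series[idx.month == 7] = 9.0
        all_junes = idx[idx.month == 6]
        sd = make_smokedays(idx, all_junes)  # every June day is smoke
        widened = nonsmoke_monthly_median(series, sd, "2011-06-15", fallback="widen")
        assert widened == 5.0  # median over pooled May (1.0) and July (9.0)
        missing = nonsmoke_monthly_median(series, sd, "2011-06-15", fallback="missing")
        assert np.isnan(missing)


class TestAttributeDay:
    @pytest.mark.parametrize("total,baseline,is_smoke,expected", [
        (10.0, 4.0, True, 6.0),    # plain deviation
        (3.0, 4.0, True, 0.0),     # negative deviation truncated to zero
        (100.0, 4.0, False, 0.0),  # non-smoke days are zero by definition
        (4.0, 4.0, True, 0.0),     # exact tie
    ])
    def test_deviation_rule(self, total, baseline, is_smoke, expected):
        assert attribute_day(total, baseline, is_smoke) == expected


def naive_attribute_grid(grid, smokedays, fallback="widen"):
    """Independent double-loop implementation: every cell, every day,
    re-deriving the pooled median from scratch."""
    rows = []
    for cell_id in sorted(grid["cell_id"].unique()):
        sub = grid[grid["cell_id"] == cell_id].set_index("date").sort_index()
        for date in sub.index:
            rec = {"cell_id": cell_id, "date": date}
            for pol, out in (("pm25", "smoke_pm25"), ("bc", "smoke_bc")):
                if smokedays.loc[date, "is_smoke"]:
                    base = naive_baseline(sub[pol], smokedays, date, fallback)
                    rec[out] = max(0.0, sub.loc[date, pol] - base) if not np.isnan(base) else np.nan
                else:
                    rec[out] = 0.0
            rows.append(rec)
    return pd.DataFrame(rows)


class TestAttributeGrid:
    def test_matches_naive_double_loop_exactly(self, small_env):
        """Vectorized attribution equals the brute-force re-implementation on
        a multi-cell three-plus-year instance, value for value."""
        grid, calendar = small_env["grid"], small_env["calendar"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = attribute_grid(grid, calendar).sort_values(["cell_id", "date"])
        want = naive_attribute_grid(grid, calendar).sort_values(["cell_id", "date"])
        np.testing.assert_allclose(got["smoke_pm25"].to_numpy(),
                                   want["smoke_pm25"].to_numpy(), rtol=0, atol=1e-12)
        np.testing.assert_allclose(got["smoke_bc"].to_numpy(),
                                   want["smoke_bc"].to_numpy(), rtol=0, atol=1e-12)

    def test_no_smoke_days_gives_all_zero(self):
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        rng = np.random.default_rng(0)
        grid = pd.DataFrame({
            "cell_id": 0, "date": idx, "pm25": rng.lognormal(1.3, 0.5, len(idx)),
            "bc": rng.lognormal(-1.8, 0.5, len(idx)),
        })
        sd = make_smokedays(idx, [])
        out = attribute_grid(grid, sd)
        assert (out["smoke_pm25"] == 0).all() and (out["smoke_bc"] == 0).all()

    def test_outputs_nonnegative_and_zero_on_nonsmoke(self, small_env):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = attribute_grid(small_env["grid"], small_env["calendar"])
        assert (out["smoke_pm25"].dropna() >= 0).all()
        nonsmoke = ~small_env["calendar"]["is_smoke"].reindex(out["date"]).to_numpy()
        assert (out.loc[nonsmoke, "smoke_pm25"] == 0).all()
        assert (out.loc[nonsmoke, "smoke_bc"] == 0).all()

    def test_missing_observations_propagate_not_zeroed(self):
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        grid = pd.DataFrame({"cell_id": 0, "date": idx, "pm25": 5.0, "bc": 0.2})
        grid.loc[grid["date"] == "2011-06-10", ["pm25", "bc"]] = np.nan
        sd = make_smokedays(idx, ["2011-06-10"])
        out = attribute_grid(grid, sd).set_index("date")
        assert np.isnan(out.loc["2011-06-10", "smoke_pm25"])

    def test_noiseless_planted_elevation_recovered_exactly(self):
        """With zero baseline noise and no spatial variation the deviation
        method returns the planted additive term exactly."""
        cfg = synthetic.SimulationConfig(
            seed=3, n_cells=2, date_range=("2009-01-01", "2011-12-31"),
            baseline_log_sd=0.0, smoke_spatial_sd=0.0)
        calendar, _ = synthetic.gen_smoke_calendar(cfg)
        grid, truth = synthetic.gen_pollutant_fields(cfg, calendar)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = attribute_grid(grid, calendar)
        merged = out.merge(truth.contributions, on=["cell_id", "date"])
        np.testing.assert_allclose(merged["smoke_pm25"], merged["planted_pm25"], atol=1e-9)
        np.testing.assert_allclose(merged["smoke_bc"], merged["planted_bc"], atol=1e-9)

    def test_median_bias_small_at_default_noise(self, small_env):
        """On noisy synthetic data the median attribution error on smoke days
        stays within 5% of the planted elevation scale."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = attribute_grid(small_env["grid"], small_env["calendar"])
        merged = out.merge(small_env["truth"].contributions, on=["cell_id", "date"])
        smoke = merged["planted_pm25"] > 0
        err = merged.loc[smoke, "smoke_pm25"] - merged.loc[smoke, "planted_pm25"]
        assert abs(err.median()) <= 0.05 * 2.41

    def test_smoke_leq_total_when_positive(self, small_env):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = attribute_grid(small_env["grid"], small_env["calendar"])
        merged = out.merge(small_env["grid"], on=["cell_id", "date"])
        pos = merged["smoke_pm25"] > 0
        assert (merged.loc[pos, "smoke_pm25"] <= merged.loc[pos, "pm25"] + 1e-9).all()


class TestRegional:
    def test_regional_equals_cell_average_on_constant_field(self):
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        rng = np.random.default_rng(4)
        vals = rng.lognormal(1.3, 0.4, len(idx))
        bc = rng.lognormal(-1.8, 0.4, len(idx))
        grid = pd.concat([
            pd.DataFrame({"cell_id": c, "date": idx, "pm25": vals, "bc": bc})
            for c in range(3)
        ], ignore_index=True)
        sd = make_smokedays(idx, idx[rng.random(len(idx)) < 0.1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reg = attribute_regional(grid, sd)
            per_cell = attribute_grid(grid, sd)
        cell_avg = per_cell.groupby("date")[["smoke_pm25", "smoke_bc"]].mean()
        np.testing.assert_allclose(reg["smoke_pm25"], cell_avg["smoke_pm25"], atol=1e-12)

    def test_weighted_mean_series(self):
        idx = pd.date_range("2010-01-01", periods=3, freq="D")
        grid = pd.concat([
            pd.DataFrame({"cell_id": 0, "date": idx, "pm25": 2.0, "bc": 0.1}),
            pd.DataFrame({"cell_id": 1, "date": idx, "pm25": 6.0, "bc": 0.3}),
        ], ignore_index=True)
        w = pd.Series({0: 3.0, 1: 1.0})
        daily = regional_mean_series(grid, weights=w)
        assert daily["pm25"].iloc[0] == pytest.approx(3.0)


class TestAttributeSeries:
    def test_baselines_stored_for_audit(self):
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        series = pd.Series(5.0, index=idx)
        series.loc["2011-06-10"] = 9.0
        sd = make_smokedays(idx, ["2011-06-10"])
        out = attribute_series(series, sd)
        assert out.loc["2011-06-10", "baseline"] == 5.0
        assert out.loc["2011-06-10", "smoke"] == 4.0
        assert np.isnan(out.loc["2011-06-11", "baseline"])
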