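"""Monthly aggregation, seasonal CV/ASV, biome comparisons and spatial bins."""

import numpy as np
import pandas as pd
import pytest

from dnrflux import fitting as F
from dnrflux import stats as S


def _fit(site, center, e0_day=None, e0_night=None, conv=True):
    """Minimal WindowFit carrying only what aggregation needs."""
    center = pd.Timestamp(center)
    w = F.Window(index=0, start=center - pd.Timedelta(days=3.5), end=center + pd.Timedelta(days=3.5), center=center)
    fit = F.WindowFit(site_id=site, window=w)
    if e0_night is not None:
        fit.night = {"r_ref_night": F.ParamPosterior(3, 2, 4), "e0_night": F.ParamPosterior(e0_night, 0, 600)}
        fit.converged_night = conv
    if e0_day is not None:
        fit.day = {
            "alpha": F.ParamPosterior(0.05, 0, 1),
            "beta0": F.ParamPosterior(20, 0, 100),
            "k": F.ParamPosterior(0.1, 0, 2),
            "r_ref_day": F.ParamPosterior(3, 2, 4),
            "e0_day": F.ParamPosterior(e0_day, 0, 600),
        }
        fit.converged_day = conv
    return fit


def _monthly_frame(site, year, delta_by_month, e0_day=200.0):
    rows = []
    for month, delta in delta_by_month.items():
        rows.append(
            {
                "site_id": site,
                "year": year,
                "month": month,
                "e0_day": e0_day,
                "e0_night": delta * e0_day if delta is not None else np.nan,
                "delta_e0": delta,
            }
        )
    return pd.DataFrame(rows)


class TestMonthlyAggregate:
    def test_single_window_passes_through(self):
        out = S.monthly_aggregate([_fit("A", "2014-06-18", e0_day=200.0, e0_night=300.0)])
        assert out.loc[0, "e0_day"] == 200.0
        assert out.loc[0, "delta_e0"] == pytest.approx(1.5)

    def test_two_windows_average(self):
        fits = [
            _fit("A", "2014-06-08", e0_day=180.0, e0_night=360.0),
            _fit("A", "2014-06-22", e0_day=220.0, e0_night=440.0),
        ]
        out = S.monthly_aggregate(fits)
        assert out.loc[0, "e0_day"] == 200.0
        assert out.loc[0, "e0_night"] == 400.0
        # ratio of monthly means, not mean of window ratios
        assert out.loc[0, "delta_e0"] == pytest.approx(2.0)

    def test_non_converged_windows_excluded_by_default(self):
        fits = [
            _fit("A", "2014-06-08", e0_day=180.0, conv=True),
            _fit("A", "2014-06-22", e0_day=900.0, conv=False),
        ]
        out = S.monthly_aggregate(fits)
        assert out.loc[0, "e0_day"] == 180.0
        all_in = S.monthly_aggregate(fits, converged_only=False)
        assert all_in.loc[0, "e0_day"] == 540.0

    def test_empty_input(self):
        assert S.monthly_aggregate([]).empty


class TestSeasonalCv:
    def test_constant_series_has_zero_cv(self):
        monthly = _monthly_frame("A", 2014, {m: 1.4 for m in range(1, 13)})
        assert S.seasonal_cv(monthly, "delta") == pytest.approx(0.0, abs=1e-9)

    def test_alternating_series_hand_value(self):
        # {100, 300} alternating: mean 200, sample sd 104.447 -> 52.22%
        vals = {m: (100.0 if m % 2 else 300.0) / 200.0 for m in range(1, 13)}
        monthly = _monthly_frame("A", 2014, vals, e0_day=200.0)
        monthly["e0_night"] = [100.0 if m % 2 else 300.0 for m in range(1, 13)]
        assert S.seasonal_cv(monthly, "night") == pytest.approx(52.22, abs=0.01)

    def test_scale_invariance(self):
        vals = {m: 1.0 + 0.1 * m for m in range(1, 13)}
        a = S.seasonal_cv(_monthly_frame("A", 2014, vals), "delta")
        scaled = _monthly_frame("A", 2014, {m: 10 * v for m, v in vals.items()})
        assert S.seasonal_cv(scaled, "delta") == pytest.approx(a)

    def test_too_few_months_is_missing(self):
        monthly = _monthly_frame("A", 2014, {m: 1.4 for m in range(1, 6)})
        assert np.isnan(S.seasonal_cv(monthly, "delta"))


class TestSeasonalAmplitude:
    def test_constant_delta_has_zero_amplitude(self):
        monthly = _monthly_frame("A", 2014, {m: 1.4 for m in range(1, 13)})
        assert S.seasonal_amplitude(monthly) == 0.0

    def test_summer_dip_amplitude(self):
        vals = {m: (1.0 if m in (6, 7, 8, 9) else 2.0) for m in range(1, 13)}
        assert S.seasonal_amplitude(_monthly_frame("A", 2014, vals)) == pytest.approx(1.0)

    def test_month_order_irrelevant(self, rng):
        vals = {m: float(v) for m, v in zip(range(1, 13), rng.uniform(1, 3, 12))}
        base = S.seasonal_amplitude(_monthly_frame("A", 2014, vals))
        perm = dict(zip(vals, rng.permutation(list(vals.values()))))
        assert S.seasonal_amplitude(_monthly_frame("A", 2014, perm)) == pytest.approx(base)


class TestDayNightTest:
    def test_identical_samples_give_t_zero_p_one(self):
        monthly = _monthly_frame("A", 2014, {m: 1.0 for m in range(1, 13)}, e0_day=200.0)
        monthly["e0_day"] = monthly["e0_night"] = 150.0 + 10.0 * monthly["month"]
        out = S.day_night_test(monthly)
        assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_doubled_nighttime_sensitivity_detected_in_every_biome(self, rng):
        # ensemble mimicking many site-months per biome with estimation noise
        frames = []
        biomes = {}
        for i, biome in enumerate(("DBF", "ENF", "GRA", "WET")):
            for j in range(200):
                site = f"S{i}{j}"
                biomes[site] = biome
                e0d = rng.normal(150, 30)
                frames.append(
                    pd.DataFrame(
                        {
                            "site_id": [site],
                            "year": [2014],
                            "month": [6],
                            "e0_day": [e0d],
                            "e0_night": [2 * 150 + rng.normal(0, 60)],
                            "delta_e0": [np.nan],
                        }
                    )
                )
        monthly = pd.concat(frames, ignore_index=True)
        out = S.day_night_test(monthly, biomes=pd.Series(biomes))
        assert len(out) == 4
        assert (out["p"] < 0.001).all()
        assert (out["difference"] > 0).all()

    def test_swapping_groups_negates_t(self):
        monthly = _monthly_frame("A", 2014, {m: 1.0 + 0.05 * m for m in range(1, 13)}, e0_day=200.0)
        out = S.day_night_test(monthly)
        swapped = monthly.rename(columns={"e0_day": "e0_night", "e0_night": "e0_day"})
        out2 = S.day_night_test(swapped)
        assert out2.loc[0, "t"] == pytest.approx(-out.loc[0, "t"])

    def test_small_groups_skipped(self):
        monthly = _monthly_frame("A", 2014, {1: 1.2, 2: 1.3})
        assert S.day_night_test(monthly).empty


class TestLatitudinalBins:
    def test_absolute_latitude_folding(self):
        summ = pd.DataFrame(
            {"site_id": ["N", "S"], "latitude": [43.7, -43.7], "asv_delta": [1.0, 2.0]}
        )
        out = S.latitudinal_bins(summ)
        assert set(out["lat_bin"]) == {40}
        assert out.loc[out["biome"] == "ALL", "n"].sum() == 2

    def test_planted_trend_preserved(self, rng):
        lats = np.repeat([5, 15, 25, 35, 45, 55], 10)
        asv = 0.02 * lats + rng.normal(0, 0.01, len(lats))
        summ = pd.DataFrame({"site_id": [f"s{i}" for i in range(len(lats))], "latitude": lats, "asv_delta": asv})
        out = S.latitudinal_bins(summ).sort_values("lat_bin")
        assert out["mean_asv"].is_monotonic_increasing

    def test_bin_counts_conserve_sites(self, rng):
        lats = rng.uniform(-70, 70, 40)
        summ = pd.DataFrame({"site_id": [f"s{i}" for i in range(40)], "latitude": lats, "asv_delta": 1.0})
        out = S.latitudinal_bins(summ)
        assert out.loc[out["biome"] == "ALL", "n"].sum() == 40


class TestClimateBins:
    def test_example_cell(self):
        summ = pd.DataFrame({"mat": [5.2], "precip_mm_day": [2.3], "asv_delta": [1.1]})
        out = S.climate_bins(summ)
        assert out.loc[0, "t_bin"] == 4.0
        assert out.loc[0, "p_bin"] == 2.0

    def test_planted_gradient_decreases_along_temperature_axis(self, rng):
        mats = np.repeat([0.0, 4.0, 8.0, 12.0, 16.0], 8)
        asv = 2.0 - 0.08 * mats + rng.normal(0, 0.02, len(mats))
        summ = pd.DataFrame({"mat": mats + 1.0, "precip_mm_day": 1.5, "asv_delta": asv})
        out = S.climate_bins(summ).sort_values("t_bin")
        assert out["mean_asv"].is_monotonic_decreasing
        assert out["n"].sum() == len(mats)


class TestThermalRegion:
    @pytest.mark.parametrize(
        "mat,region",
        [(1.0, "boreal"), (2.0, "temperate"), (17.0, "temperate"), (17.01, "tropical"), (-20.0, "boreal")],
    )
    def test_boundary_rules(self, mat, region):
        assert S.thermal_region(mat) == region

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            S.thermal_region(float("nan"))


class TestSeasonalSummary:
    def test_one_row_per_site_year(self):
        m1 = _monthly_frame("A", 2014, {m: 1.0 + 0.05 * m for m in range(1, 13)})
        m2 = _monthly_frame("B", 2015, {m: 2.0 for m in range(1, 13)})
        out = S.seasonal_summary(pd.concat([m1, m2], ignore_index=True))
        assert len(out) == 2
        b = out[out["site_id"] == "B"].iloc[0]
        assert b["asv_delta"] == 0.0 and b["cv_delta"] == 0.0
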