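"""Window enumeration, MCMC/NLS estimation, ε determination, baselines and
ER reconstruction."""

import numpy as np
import pandas as pd
import pytest

import dnrflux as d
from dnrflux import fitting as F
from dnrflux import simulate

FAST = d.FitConfig(n_iter=2000, seed=42)


def _window_df(series, window):
    df = series.data
    out = df[(df["timestamp"] >= window.start) & (df["timestamp"] < window.end)].copy()
    out["rh_bar"] = F.assign_window_rh_mean(series)[out.index]
    return out


class TestMakeWindows:
    def test_seven_day_windows_five_day_step_over_thirty_days(self):
        drv = d.generate_drivers(30, 45.0, seed=1)
        windows = F.make_windows(drv, F.WindowSpec(window_days=7, step_days=5))
        starts = [(w.start - drv.data["timestamp"].iloc[0].normalize()).days for w in windows]
        assert starts == [0, 5, 10, 15, 20]

    def test_step_equals_window_tiles_disjointly(self):
        drv = d.generate_drivers(21, 45.0, seed=1)
        windows = F.make_windows(drv, F.WindowSpec(window_days=7, step_days=7))
        assert len(windows) == 3
        for a, b in zip(windows, windows[1:]):
            assert a.end == b.start

    def test_series_shorter_than_window_gives_nothing(self):
        drv = d.generate_drivers(3, 45.0, seed=1)
        assert F.make_windows(drv, F.WindowSpec(window_days=7, step_days=5)) == []

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            F.WindowSpec(window_days=3, step_days=5)


class TestNightFit:
    def test_noisefree_recovery_within_one_percent(self, noisefree_series):
        series, truth = noisefree_series
        w = F.make_windows(series)[0]
        res = F.fit_night_window(_window_df(series, w), FAST)
        assert res.params.e0_night == pytest.approx(320.0, rel=0.01)
        assert res.params.r_ref_night == pytest.approx(3.0, rel=0.01)
        assert res.rmse < 1e-6

    def test_posterior_median_matches_nls_oracle(self, noisefree_series):
        series, _ = noisefree_series
        w = F.make_windows(series)[1]
        df = _window_df(series, w)
        night = df[~df["is_day"] & df["nee"].notna()]
        nls = F.nls_fit_night(night["tair"].to_numpy(), night["nee"].to_numpy(), config=FAST)
        res = F.fit_night_window(df, FAST)
        assert res.params.r_ref_night == pytest.approx(nls["x"][0], rel=0.01)
        assert res.params.e0_night == pytest.approx(nls["x"][1], rel=0.01)

    def test_isothermal_window_skipped(self, noisefree_series):
        series, _ = noisefree_series
        w = F.make_windows(series)[0]
        df = _window_df(series, w)
        df["tair"] = 12.0
        assert F.fit_night_window(df, FAST) is None

    def test_too_few_records_skipped(self, noisefree_series):
        series, _ = noisefree_series
        w = F.make_windows(series)[0]
        df = _window_df(series, w).iloc[:40]
        assert F.fit_night_window(df, FAST, min_obs=500) is None


class TestDayFit:
    def test_noisefree_recovery_within_five_percent(self, noisefree_series):
        series, truth = noisefree_series
        w = F.make_windows(series)[0]
        res = F.fit_day_window(_window_df(series, w), epsilon=1, config=FAST)
        expected = {"alpha": 0.05, "beta0": 20.0, "k": 0.1, "r_ref_day": 3.0, "e0_day": 150.0}
        for name, value in expected.items():
            assert res.posterior[name].median == pytest.approx(value, rel=0.05), name

    def test_k_pinned_when_vpd_never_exceeds_threshold(self, noisefree_series):
        series, _ = noisefree_series
        w = F.make_windows(series)[0]
        df = _window_df(series, w)
        df["vpd"] = 5.0
        res = F.fit_day_window(df, epsilon=1, config=FAST)
        assert res.k_pinned
        assert res.posterior["k"].median == 0.0

    def test_same_seed_identical_output(self, noisy_series):
        series, _ = noisy_series
        w = F.make_windows(series)[2]
        df = _window_df(series, w)
        a = F.fit_day_window(df, epsilon=1, config=FAST, rng=np.random.default_rng(5))
        b = F.fit_day_window(df, epsilon=1, config=FAST, rng=np.random.default_rng(5))
        assert a.posterior == b.posterior


class TestEpsilon:
    def test_planted_decreasing_relation_gives_minus_one(self):
        rh = np.linspace(40, 90, 12)
        assert F.estimate_epsilon(2.0 - 0.01 * rh, rh) == -1

    def test_planted_increasing_relation_gives_plus_one(self):
        rh = np.linspace(40, 90, 12)
        assert F.estimate_epsilon(1.0 + 0.01 * rh, rh) == 1

    def test_constant_ratio_takes_otherwise_branch(self):
        # zero correlation (constant input) is not a negative correlation
        rh = np.linspace(40, 90, 8)
        assert F.estimate_epsilon(np.full(8, 1.3), rh) == 1

    def test_fewer_than_five_windows_defaults_with_warning(self):
        with pytest.warns(UserWarning):
            assert F.estimate_epsilon([1.0, 1.1], [50.0, 60.0]) == 1


class TestBaselines:
    def test_nt_shares_night_fit_code_path(self, noisy_series):
        series, _ = noisy_series
        spec = F.WindowSpec()
        nt = F.fit_nt_baseline(series, spec, FAST)
        w = nt.fits[0].window
        manual = F.fit_night_window(
            _window_df(series, w), FAST, rng=F._window_rng(FAST, w.index, 0)
        )
        assert nt.fits[0].night == manual.posterior

    def test_dt_pins_e0_to_nighttime_estimate(self, noisy_series):
        series, _ = noisy_series
        dt = F.fit_dt_baseline(series, F.WindowSpec(), FAST)
        for f in dt.fits:
            if f.day is not None:
                assert f.day["e0_day"].median == pytest.approx(f.night["e0_night"].median)

    def test_dtrh_fits_daytime_data_better_than_dt_under_humidity_modulation(self, noisy_series):
        series, _ = noisy_series
        dtrh = d.fit_site(series, config=FAST, epsilon=1)
        dt = F.fit_dt_baseline(series, F.WindowSpec(), FAST)
        rmse_dtrh = np.nanmean([f.rmse_day for f in dtrh.fits if f.day])
        rmse_dt = np.nanmean([f.rmse_day for f in dt.fits if f.day])
        assert rmse_dtrh < rmse_dt


class TestErSeries:
    def test_noisefree_reconstruction_tracks_truth(self, noisefree_series):
        series, truth = noisefree_series
        res = d.fit_site(series, config=FAST, epsilon=1)
        er = d.estimate_er_series(res.fits, series)
        true = simulate.true_er(series, truth)
        covered = er.er.notna()
        assert covered.sum() > 0.85 * len(series)
        np.testing.assert_allclose(er.er[covered], true[covered], rtol=0.02, atol=0.02)
        assert (er.er.dropna() >= 0).all()

    def test_records_outside_window_coverage_are_missing(self, noisefree_series):
        series, _ = noisefree_series
        res = d.fit_site(series, config=FAST, epsilon=1)
        er = d.estimate_er_series(res.fits, series)
        last_end = max(f.window.end for f in res.fits)
        tail = series.data["timestamp"] >= last_end
        assert tail.any() and er.er[tail].isna().all()

    def test_identical_fits_give_zero_bias(self, noisefree_series):
        series, _ = noisefree_series
        res = d.fit_site(series, config=FAST, epsilon=1)
        bias = d.er_bias_ignoring_delta(series, res.fits, res.fits)
        assert bias.abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_no_fits_rejected(self, noisefree_series):
        series, _ = noisefree_series
        with pytest.raises(ValueError):
            d.estimate_er_series([], series)


class TestDeterminism:
    def test_full_fit_pipeline_bit_reproducible(self, noisy_series):
        series, _ = noisy_series
        a = d.fits_to_frame(d.fit_site(series, config=FAST, epsilon=1))
        b = d.fits_to_frame(d.fit_site(series, config=FAST, epsilon=1))
        pd.testing.assert_frame_equal(a, b)


class TestFitsFrame:
    def test_one_row_per_window_with_posterior_columns(self, noisy_series):
        series, _ = noisy_series
        res = d.fit_site(series, config=FAST, epsilon=1)
        frame = d.fits_to_frame(res)
        assert len(frame) == len(res.fits)
        for col in ("e0_day_median", "e0_night_median", "e0_night_lo", "e0_night_hi", "converged_night"):
            assert col in frame.columns
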