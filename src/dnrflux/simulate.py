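"""Synthetic flux-tower generator: FLUXNET-like drivers and NEE from the
DT-RH forward model with prescribed day/night parameter trajectories.

The generator is the ground truth for every recovery test in the package.
Radiation follows clear-sky solar geometry with daily cloud dimming; air
temperature combines a latitude-dependent seasonal sinusoid, a diurnal
cycle lagging radiation by about two hours, and autocorrelated weather
noise; relative humidity is anti-correlated with the diurnal temperature
anomaly; VPD follows from temperature and RH through the saturated vapour
pressure. NEE is the forward model evaluated on per-day parameter
trajectories plus Gaussian observation noise, with a configurable fraction
of records flagged as gap-filled (qc = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .fitting import WindowSpec, assign_window_rh_mean
from .flux_io import SW_DAY_THRESHOLD, FluxSeries, flag_day_night
from .model import (
    DEFAULT_CONSTANTS,
    DayParams,
    DriverSlice,
    ModelConstants,
    NightParams,
    daytime_er,
    lloyd_taylor,
    predict_nee,
)

__all__ = [
    "SyntheticTruth",
    "constant_truth",
    "seasonal_truth",
    "DEFAULT_SCENARIO",
    "generate_drivers",
    "generate_nee",
    "true_er",
    "write_csv",
    "saturation_vapour_pressure",
]

_PARAM_COLS = ["alpha", "beta0", "k", "r_ref_day", "e0_day", "r_ref_night", "e0_night"]


@dataclass
class SyntheticTruth:
    """Prescribed parameter trajectories and noise structure.

    ``params`` has one row per simulated calendar day (DatetimeIndex,
    normalized) and the columns alpha, beta0, k, r_ref_day, e0_day,
    r_ref_night, e0_night; ``epsilon`` is the site humidity sign.
    ``noise_sd`` is the Gaussian observation noise on NEE
    (µmol C m⁻² s⁻¹); ``missing_fraction`` of records are flagged qc = 1.
    """

    params: pd.DataFrame
    epsilon: int = 1
    latitude: float = 45.0
    noise_sd: float = 1.0
    missing_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in _PARAM_COLS if c not in self.params.columns]
        if missing:
            raise ValueError(f"truth trajectories missing columns: {missing}")
        if self.noise_sd < 0 or not (0 <= self.missing_fraction <= 1):
            raise ValueError("noise_sd must be >= 0 and missing_fraction in [0, 1]")

    def day_params_at(self, dates: pd.DatetimeIndex) -> pd.DataFrame:
        return self.params.loc[dates.normalize()]


def _dates(n_days: int, start: str) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n_days, freq="D")


def constant_truth(
    n_days: int,
    start: str = "2014-01-01",
    alpha: float = 0.05,
    beta0: float = 20.0,
    k: float = 0.1,
    r_ref_day: float = 3.0,
    e0_day: float = 150.0,
    r_ref_night: float = 3.0,
    e0_night: float = 320.0,
    epsilon: int = 1,
    latitude: float = 45.0,
    noise_sd: float = 1.0,
    missing_fraction: float = 0.1,
    seed: int = 0,
) -> SyntheticTruth:
    """Time-constant parameter trajectories (the simplest recovery target)."""
    dates = _dates(n_days, start)
    params = pd.DataFrame(
        {
            "alpha": alpha,
            "beta0": beta0,
            "k": k,
            "r_ref_day": r_ref_day,
            "e0_day": e0_day,
            "r_ref_night": r_ref_night,
            "e0_night": e0_night,
        },
        index=dates,
    )
    return SyntheticTruth(params, epsilon, latitude, noise_sd, missing_fraction, seed)


#: Monthly anchor values for the default northern-hemisphere scenario:
#: daytime temperature sensitivity peaks June-September while nighttime
#: sensitivity dips, so the day-night ratio ΔE₀ exceeds 1 outside summer
#: and approaches (or slightly undershoots) 1 within it.
DEFAULT_SCENARIO = {
    "alpha": [0.04] * 12,
    "beta0": [6, 8, 12, 16, 22, 26, 28, 26, 20, 14, 8, 6],
    "k": [0.1] * 12,
    "r_ref_day": [1.5, 1.6, 2.0, 2.6, 3.2, 3.8, 4.0, 3.8, 3.2, 2.4, 1.8, 1.5],
    "e0_day": [100, 105, 115, 130, 150, 170, 180, 175, 160, 130, 110, 100],
    "r_ref_night": [1.5, 1.6, 2.0, 2.6, 3.2, 3.8, 4.0, 3.8, 3.2, 2.4, 1.8, 1.5],
    "e0_night": [300, 295, 280, 250, 200, 165, 155, 160, 185, 240, 280, 295],
}


def seasonal_truth(
    n_days: int,
    start: str = "2014-01-01",
    monthly: dict[str, list[float]] | None = None,
    epsilon: int = 1,
    latitude: float = 45.0,
    noise_sd: float = 1.0,
    missing_fraction: float = 0.1,
    seed: int = 0,
) -> SyntheticTruth:
    """Trajectories from 12 monthly anchor values, linearly interpolated
    between month centers (periodic across year boundaries)."""
    monthly = {**DEFAULT_SCENARIO, **(monthly or {})}
    dates = _dates(n_days, start)
    doy = dates.dayofyear.to_numpy(float)
    centers = np.array([15.5, 45, 74.5, 105, 135.5, 166, 196.5, 227.5, 258, 288.5, 319, 349.5])
    cols = {}
    for name in _PARAM_COLS:
        vals = np.asarray(monthly[name], float)
        if len(vals) != 12:
            raise ValueError(f"{name}: need 12 monthly anchors")
        xp = np.concatenate([[centers[-1] - 365.25], centers, [centers[0] + 365.25]])
        fp = np.concatenate([[vals[-1]], vals, [vals[0]]])
        cols[name] = np.interp(doy, xp, fp)
    params = pd.DataFrame(cols, index=dates)
    return SyntheticTruth(params, epsilon, latitude, noise_sd, missing_fraction, seed)


def saturation_vapour_pressure(tair_c) -> np.ndarray:
    """Magnus saturated vapour pressure over water, hPa."""
    tair_c = np.asarray(tair_c, float)
    return 6.1078 * np.exp(17.269 * tair_c / (237.3 + tair_c))


def generate_drivers(
    n_days: int,
    latitude: float,
    seed: int,
    step_minutes: int = 30,
    start: str = "2014-01-01",
    site_id: str = "SYN-01",
    biome: str = "GRA",
    rh_base_mean: float = 72.0,
) -> FluxSeries:
    """Generate half-hourly meteorological drivers for a synthetic tower.

    ``rh_base_mean`` sets the mean daily relative-humidity baseline (%);
    lower values emulate drier climates with more frequent VPD limitation.

    Returns a :class:`FluxSeries` with NEE missing, qc 0 everywhere and
    day/night flags already attached. Deterministic for fixed ``seed``.
    """
    if not (1 <= n_days <= 3660):
        raise ValueError("n_days must be in [1, 3660]")
    if not abs(latitude) <= 90:
        raise ValueError("latitude must be in [-90, 90]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(101,)))
    steps_per_day = int(24 * 60 / step_minutes)
    n = n_days * steps_per_day
    ts = pd.date_range(start, periods=n, freq=f"{step_minutes}min")
    doy = ts.dayofyear.to_numpy(float)
    hour = ts.hour.to_numpy(float) + ts.minute.to_numpy(float) / 60.0 + step_minutes / 120.0
    day_index = np.repeat(np.arange(n_days), steps_per_day)

    # clear-sky radiation from solar geometry, dimmed by a daily cloud factor
    phi = np.deg2rad(latitude)
    decl = np.deg2rad(-23.44 * np.cos(2 * np.pi * (doy + 10) / 365.25))
    hour_angle = np.deg2rad(15.0 * (hour - 12.0))
    cos_zen = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(hour_angle)
    cloud = rng.uniform(0.35, 1.0, size=n_days)
    sw_in = 1000.0 * cloud[day_index] * np.maximum(cos_zen, 0.0)

    # air temperature: seasonal cycle + synoptic (daily AR(1)) warm/cold
    # spells + diurnal cycle lagging solar noon ~2 h + fast AR(1) noise
    mat = 27.0 - 0.42 * abs(latitude)
    seas_amp = 2.0 + 0.28 * abs(latitude)
    peak_doy = 202.0 if latitude >= 0 else 20.0
    seasonal = mat + seas_amp * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)
    synoptic = lfilter([1.0], [1.0, -0.8], rng.normal(0.0, 2.2, size=n_days))
    # full diurnal range ~6-10 degC (larger on clear days), typical of
    # mid-latitude towers
    diurnal_amp = 4.5 + 5.5 * cloud[day_index]
    diurnal = 0.5 * diurnal_amp * -np.cos(2 * np.pi * (hour - 2.0) / 24.0)
    ar = lfilter([1.0], [1.0, -0.95], rng.normal(0.0, 0.25, size=n))
    tair = seasonal + synoptic[day_index] + diurnal + ar

    # RH anti-correlated with the diurnal temperature anomaly
    rh_base = np.clip(rng.normal(rh_base_mean, 8.0, size=n_days), 25.0, 95.0)
    daily_mean_t = np.add.reduceat(tair, np.arange(0, n, steps_per_day)) / steps_per_day
    rh = rh_base[day_index] - 2.2 * (tair - daily_mean_t[day_index]) + rng.normal(0.0, 3.0, size=n)
    rh = np.clip(rh, 15.0, 100.0)
    vpd = saturation_vapour_pressure(tair) * (1.0 - rh / 100.0)

    wet = rng.random(n_days) < 0.25
    amount = rng.exponential(5.0, size=n_days) * wet
    precip = np.clip(rng.random(n) * 2.0 / steps_per_day, 0, None) * amount[day_index]

    df = pd.DataFrame(
        {
            "timestamp": ts,
            "nee": np.nan,
            "tair": tair,
            "sw_in": sw_in,
            "vpd": vpd,
            "rh": rh,
            "precip": precip,
            "qc_nee": 0,
        }
    )
    series = FluxSeries(
        site_id=site_id, latitude=latitude, longitude=0.0, biome=biome, step_minutes=step_minutes, data=df
    )
    return flag_day_night(series, SW_DAY_THRESHOLD)


def _truth_arrays(drivers: FluxSeries, truth: SyntheticTruth):
    dates = pd.DatetimeIndex(drivers.data["timestamp"]).normalize()
    if not dates.isin(truth.params.index).all():
        raise ValueError("truth trajectories do not cover the driver span")
    rows = truth.params.loc[dates]
    day_p = DayParams(
        alpha=rows["alpha"].to_numpy(),
        beta0=rows["beta0"].to_numpy(),
        k=rows["k"].to_numpy(),
        r_ref_day=rows["r_ref_day"].to_numpy(),
        e0_day=rows["e0_day"].to_numpy(),
        epsilon=truth.epsilon,
    )
    night_p = NightParams(
        r_ref_night=rows["r_ref_night"].to_numpy(),
        e0_night=rows["e0_night"].to_numpy(),
    )
    return day_p, night_p


def generate_nee(
    drivers: FluxSeries,
    truth: SyntheticTruth,
    spec: WindowSpec = WindowSpec(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> FluxSeries:
    """Evaluate the forward model on the drivers and add observation noise.

    RH̄ is computed with the same moving-window scheme the fitter uses, so
    a noise-free series is exactly invertible by the forward model. A
    ``missing_fraction`` of records receive qc = 1 (treated as gap-filled
    downstream and excluded from fitting by the default QC policy).
    """
    day_p, night_p = _truth_arrays(drivers, truth)
    rh_bar = assign_window_rh_mean(drivers, spec)
    df = drivers.data
    sl = DriverSlice(
        q=df["sw_in"].to_numpy(),
        tair=df["tair"].to_numpy(),
        vpd=df["vpd"].to_numpy(),
        rh=df["rh"].to_numpy(),
        rh_window_mean=rh_bar,
    )
    nee = predict_nee(day_p, night_p, sl, df["is_day"].to_numpy(bool), constants)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=truth.seed, spawn_key=(202,)))
    if truth.noise_sd > 0:
        nee = nee + rng.normal(0.0, truth.noise_sd, size=len(nee))
    qc = np.zeros(len(nee), dtype=int)
    if truth.missing_fraction > 0:
        qc[rng.random(len(nee)) < truth.missing_fraction] = 1
    out = drivers.copy()
    out.data["nee"] = nee
    out.data["qc_nee"] = qc
    return out


def true_er(
    drivers: FluxSeries,
    truth: SyntheticTruth,
    spec: WindowSpec = WindowSpec(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> pd.Series:
    """Noise-free ER implied by the truth trajectories, for scoring
    reconstructions (daytime records include the humidity factor)."""
    day_p, night_p = _truth_arrays(drivers, truth)
    rh_bar = assign_window_rh_mean(drivers, spec)
    df = drivers.data
    sl = DriverSlice(
        q=df["sw_in"].to_numpy(),
        tair=df["tair"].to_numpy(),
        vpd=df["vpd"].to_numpy(),
        rh=df["rh"].to_numpy(),
        rh_window_mean=rh_bar,
    )
    is_day = df["is_day"].to_numpy(bool)
    er_day = daytime_er(day_p, sl, constants)
    er_night = lloyd_taylor(night_p.r_ref_night, night_p.e0_night, sl.tair, constants)
    return pd.Series(np.where(is_day, er_day, er_night), index=df.index, name="er_true")


def write_csv(series: FluxSeries, path) -> None:
    """Write a FLUXNET2015-dialect CSV (TIMESTAMP_START as YYYYMMDDHHMM,
    −9999 for missing) readable by :func:`dnrflux.flux_io.read_fluxnet_csv`."""
    df = series.data
    out = pd.DataFrame(
        {
            "TIMESTAMP_START": df["timestamp"].dt.strftime("%Y%m%d%H%M"),
            "NEE_VUT_USTAR50": df["nee"],
            "TA_F": df["tair"],
            "SW_IN_F": df["sw_in"],
            "VPD_F": df["vpd"],
            "RH": df["rh"],
            "P_F": df["precip"],
            "NEE_VUT_USTAR50_QC": df["qc_nee"],
        }
    )
    out.to_csv(path, index=False, na_rep="-9999", float_format="%.10g")
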