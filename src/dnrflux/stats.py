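"""Seasonal and cross-site statistics of the day/night temperature-sensitivity asymmetry.

Window fits are averaged to site-months; the diel discrepancy is the ratio
of monthly means, ΔE₀ = E₀,night/E₀,day (> 1: respiration more
temperature-sensitive at night).  Seasonality is summarized per site-year
by the coefficient of variation (CV, %) of the monthly values and by the
seasonal amplitude ASV (max − min of monthly ΔE₀ within a calendar year).
Cross-site structure: Welch t-tests of E₀,night vs E₀,day per biome,
10°-wide absolute-latitude bins, a 4 °C × 1 mm day⁻¹ climate grid, and the
boreal/temperate/tropical classification on mean annual temperature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .fitting import WindowFit

__all__ = [
    "monthly_aggregate",
    "seasonal_cv",
    "seasonal_amplitude",
    "seasonal_summary",
    "day_night_test",
    "latitudinal_bins",
    "climate_bins",
    "thermal_region",
]


def monthly_aggregate(fits: list[WindowFit], converged_only: bool = True) -> pd.DataFrame:
    """Average window estimates of E₀ to site-months.

    Windows contribute to the month their center falls in.  Monthly
    ``e0_day``/``e0_night`` are arithmetic means over converged window
    estimates (set ``converged_only=False`` to include all); ``delta_e0``
    is the ratio of the monthly means, not the mean of window ratios —
    less noise amplification when E₀,day is small.  Columns: site_id,
    year, month, e0_day, e0_night, delta_e0, n_windows_day,
    n_windows_night.
    """
    rows = []
    for f in fits:
        use_day = f.day is not None and (f.converged_day or not converged_only)
        use_night = f.night is not None and (f.converged_night or not converged_only)
        if not (use_day or use_night):
            continue
        rows.append(
            {
                "site_id": f.site_id,
                "year": f.window.center.year,
                "month": f.window.center.month,
                "e0_day": f.day["e0_day"].median if use_day else np.nan,
                "e0_night": f.night["e0_night"].median if use_night else np.nan,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["site_id", "year", "month", "e0_day", "e0_night", "delta_e0", "n_windows_day", "n_windows_night"]
        )
    df = pd.DataFrame(rows)
    grp = df.groupby(["site_id", "year", "month"])
    out = grp.agg(
        e0_day=("e0_day", "mean"),
        e0_night=("e0_night", "mean"),
        n_windows_day=("e0_day", "count"),
        n_windows_night=("e0_night", "count"),
    ).reset_index()
    out["delta_e0"] = out["e0_night"] / out["e0_day"]
    cols = ["site_id", "year", "month", "e0_day", "e0_night", "delta_e0", "n_windows_day", "n_windows_night"]
    return out[cols]


def monthly_aggregate_from_frame(fits: pd.DataFrame, converged_only: bool = True) -> pd.DataFrame:
    """Same monthly aggregation as :func:`monthly_aggregate` but from the
    tidy fits table written by the ``fit`` command."""
    df = fits.copy()
    center = pd.to_datetime(df["center"])
    df["year"] = center.dt.year
    df["month"] = center.dt.month
    if converged_only:
        df.loc[~df["converged_day"].astype(bool), "e0_day_median"] = np.nan
        df.loc[~df["converged_night"].astype(bool), "e0_night_median"] = np.nan
    grp = df.groupby(["site_id", "year", "month"])
    out = grp.agg(
        e0_day=("e0_day_median", "mean"),
        e0_night=("e0_night_median", "mean"),
        n_windows_day=("e0_day_median", "count"),
        n_windows_night=("e0_night_median", "count"),
    ).reset_index()
    out["delta_e0"] = out["e0_night"] / out["e0_day"]
    cols = ["site_id", "year", "month", "e0_day", "e0_night", "delta_e0", "n_windows_day", "n_windows_night"]
    return out[cols]


def _one_site_year(monthly: pd.DataFrame) -> pd.DataFrame:
    if monthly[["site_id", "year"]].drop_duplicates().shape[0] > 1:
        raise ValueError("expected records of a single site-year")
    return monthly


def seasonal_cv(monthly: pd.DataFrame, which: str = "delta", min_months: int = 8) -> float:
    """Seasonal coefficient of variation (%) of monthly E₀ for one site-year.

    100 · sd/mean over the non-missing monthly values of ``e0_day``
    (which="day"), ``e0_night`` ("night") or ``delta_e0`` ("delta"); sd is
    the sample standard deviation. NaN when fewer than ``min_months``
    months are available.
    """
    col = {"day": "e0_day", "night": "e0_night", "delta": "delta_e0"}[which]
    vals = _one_site_year(monthly)[col].dropna().to_numpy(float)
    if len(vals) < min_months:
        return np.nan
    return float(100.0 * vals.std(ddof=1) / vals.mean())


def seasonal_amplitude(monthly: pd.DataFrame, min_months: int = 8) -> float:
    """Seasonal amplitude ΔE₀,ASV for one site-year: the difference between
    the highest and lowest monthly ΔE₀ within the calendar year (order-free,
    non-negative). NaN when fewer than ``min_months`` months are present."""
    vals = _one_site_year(monthly)["delta_e0"].dropna().to_numpy(float)
    if len(vals) < min_months:
        return np.nan
    return float(vals.max() - vals.min())


def seasonal_summary(monthly: pd.DataFrame, min_months: int = 8) -> pd.DataFrame:
    """Per site-year seasonal statistics: CV (%) of monthly E₀,day,
    E₀,night and ΔE₀, plus the seasonal amplitude of ΔE₀."""
    rows = []
    for (site, year), grp in monthly.groupby(["site_id", "year"]):
        rows.append(
            {
                "site_id": site,
                "year": year,
                "cv_day": seasonal_cv(grp, "day", min_months),
                "cv_night": seasonal_cv(grp, "night", min_months),
                "cv_delta": seasonal_cv(grp, "delta", min_months),
                "asv_delta": seasonal_amplitude(grp, min_months),
                "n_months": int(grp["delta_e0"].notna().sum()),
            }
        )
    return pd.DataFrame(rows)


def day_night_test(monthly: pd.DataFrame, biomes: pd.Series | None = None, min_n: int = 3) -> pd.DataFrame:
    """Welch two-sample t-test of E₀,night vs E₀,day per biome.

    ``biomes`` maps site_id to biome code; without it, all records form a
    single "ALL" group. Positive t (and difference) means nighttime E₀
    exceeds daytime E₀. Groups with fewer than ``min_n`` paired records
    are skipped.
    """
    df = monthly.copy()
    if biomes is not None:
        df["biome"] = df["site_id"].map(biomes)
    else:
        df["biome"] = "ALL"
    rows = []
    for biome, grp in df.groupby("biome"):
        night = grp["e0_night"].dropna().to_numpy(float)
        day = grp["e0_day"].dropna().to_numpy(float)
        if len(night) < min_n or len(day) < min_n:
            continue
        t, p = ttest_ind(night, day, equal_var=False)
        rows.append(
            {
                "biome": biome,
                "mean_e0_night": night.mean(),
                "mean_e0_day": day.mean(),
                "difference": night.mean() - day.mean(),
                "t": float(t),
                "p": float(p),
                "n_night": len(night),
                "n_day": len(day),
            }
        )
    return pd.DataFrame(rows)


def latitudinal_bins(summaries: pd.DataFrame, bin_width: float = 10.0) -> pd.DataFrame:
    """Mean multi-year ΔE₀,ASV in absolute-latitude bins [0,10), [10,20), …

    ``summaries`` needs columns site_id, latitude, asv_delta (and
    optionally biome for per-biome means; a pooled "ALL" row set is always
    produced). Sites in both hemispheres fold onto the same bin.
    """
    df = summaries.copy()
    df["lat_bin"] = (np.abs(df["latitude"]) // bin_width).astype(int) * bin_width
    if "biome" not in df.columns:
        df["biome"] = "ALL"
    pooled = df.assign(biome="ALL")
    both = pd.concat([df, pooled]) if (df["biome"] != "ALL").any() else pooled
    out = (
        both.groupby(["biome", "lat_bin"])["asv_delta"]
        .agg(mean_asv="mean", n="count")
        .reset_index()
        .sort_values(["biome", "lat_bin"])
        .reset_index(drop=True)
    )
    return out


def climate_bins(
    summaries: pd.DataFrame, t_width: float = 4.0, p_width: float = 1.0
) -> pd.DataFrame:
    """Mean ΔE₀,ASV on a rectangular climate grid.

    Bins are ``t_width`` °C of mean annual temperature by ``p_width``
    mm day⁻¹ of precipitation; cells carry the per-cell mean and count
    (cells without sites are absent from the table, i.e. count 0).
    Needs columns mat, precip_mm_day, asv_delta.
    """
    df = summaries.copy()
    df["t_bin"] = np.floor(df["mat"] / t_width) * t_width
    df["p_bin"] = np.floor(df["precip_mm_day"] / p_width) * p_width
    return (
        df.groupby(["t_bin", "p_bin"])["asv_delta"]
        .agg(mean_asv="mean", n="count")
        .reset_index()
    )


def thermal_region(mat: float) -> str:
    """Thermal classification on mean annual temperature: boreal
    (MAT < 2 °C), temperate (2 ≤ MAT ≤ 17 °C), tropical (MAT > 17 °C)."""
    if not np.isfinite(mat):
        raise ValueError("MAT must be finite")
    if mat < 2.0:
        return "boreal"
    if mat <= 17.0:
        return "temperate"
    return "tropical"
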