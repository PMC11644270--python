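"""Reading, QC filtering and annotation of FLUXNET2015-style half-hourly records.

A :class:`FluxSeries` wraps a pandas DataFrame with one row per half-hourly
(or hourly) interval and the canonical columns ``timestamp, nee, tair,
sw_in, vpd, rh, precip, qc_nee, is_day`` plus site metadata.  Timestamps
are tower local standard time and denote the interval start
(FLUXNET ``TIMESTAMP_START`` convention).  NEE is in µmol C m⁻² s⁻¹ with
release to the atmosphere positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "BIOMES",
    "FluxSeries",
    "read_fluxnet_csv",
    "gap_fill_rh",
    "flag_day_night",
    "qc_filter",
    "DEFAULT_COLUMN_MAP",
    "SW_DAY_THRESHOLD",
]

#: IGBP-style biome codes of the nine ecosystem classes handled here.
BIOMES = ("CRO", "DBF", "EBF", "ENF", "MF", "GRA", "SAV", "SH", "WET")

#: Shortwave threshold (W m⁻²) above which a record counts as daytime.
SW_DAY_THRESHOLD = 20.0

#: FLUXNET2015 column names mapped onto the canonical schema.
DEFAULT_COLUMN_MAP = {
    "TIMESTAMP_START": "timestamp",
    "NEE_VUT_USTAR50": "nee",
    "TA_F": "tair",
    "SW_IN_F": "sw_in",
    "VPD_F": "vpd",
    "RH": "rh",
    "P_F": "precip",
    "NEE_VUT_USTAR50_QC": "qc_nee",
}

_CANONICAL = ["timestamp", "nee", "tair", "sw_in", "vpd", "rh", "precip", "qc_nee"]


@dataclass
class FluxSeries:
    """Half-hourly flux-tower record collection for one site.

    ``data`` holds the canonical columns; ``is_day`` is added by
    :func:`flag_day_night`. Metadata: ``site_id``, ``latitude``,
    ``longitude``, ``biome`` (one of :data:`BIOMES`), ``step_minutes``.
    """

    site_id: str
    latitude: float
    longitude: float
    biome: str
    step_minutes: int
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.biome not in BIOMES:
            raise ValueError(f"biome {self.biome!r} not one of {BIOMES}")
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing = [c for c in _CANONICAL if c not in df.columns]
        if missing:
            raise ValueError(f"missing canonical columns: {missing}")
        ts = df["timestamp"]
        if ts.duplicated().any():
            raise ValueError("duplicate timestamps")
        steps = ts.diff().dropna()
        expected = pd.Timedelta(minutes=self.step_minutes)
        if len(steps) and not (steps == expected).all():
            raise ValueError("timestamps not strictly increasing at a constant step")
        if self.step_minutes not in (30, 60):
            raise ValueError("step_minutes must be 30 or 60")
        for col, lo in (("sw_in", 0.0), ("vpd", 0.0), ("precip", 0.0)):
            vals = df[col].dropna()
            if (vals < lo).any():
                raise ValueError(f"{col} contains values below {lo}")
        rh = df["rh"].dropna()
        if ((rh < 0) | (rh > 100)).any():
            raise ValueError("rh outside [0, 100]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def step_seconds(self) -> float:
        return self.step_minutes * 60.0

    def copy(self) -> "FluxSeries":
        return replace(self, data=self.data.copy())


def read_fluxnet_csv(
    path,
    column_map: dict | None = None,
    missing_code: float = -9999.0,
    site_id: str = "SITE",
    latitude: float = 0.0,
    longitude: float = 0.0,
    biome: str = "GRA",
) -> FluxSeries:
    """Read a FLUXNET2015-dialect CSV into a :class:`FluxSeries`.

    ``column_map`` maps file column names to the canonical schema and
    defaults to the FLUXNET2015 names; values equal to ``missing_code``
    become NaN.  The time step is inferred from consecutive timestamps and
    validated to be constant (30 or 60 min).  Site metadata is not carried
    in FLUXNET data files and is supplied by the caller.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    df = pd.read_csv(path, dtype={next(k for k, v in column_map.items() if v == "timestamp"): str})
    missing_cols = [c for c in column_map if c not in df.columns]
    if missing_cols:
        raise ValueError(f"schema error: required columns absent: {missing_cols}")
    df = df[list(column_map)].rename(columns=column_map)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="%Y%m%d%H%M")
    except ValueError as exc:
        bad = df.loc[pd.to_datetime(df["timestamp"], format="%Y%m%d%H%M", errors="coerce").isna()]
        row = int(bad.index[0]) if len(bad) else -1
        raise ValueError(f"parse error: malformed timestamp at data row {row}") from exc
    df = df.sort_values("timestamp").reset_index(drop=True)
    for col in df.columns:
        if col == "timestamp":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        df[col] = vals.mask(vals == missing_code)
    steps = df["timestamp"].diff().dropna().dt.total_seconds() / 60.0
    if len(steps) == 0:
        raise ValueError("structure error: need at least two rows to infer the step")
    if steps.nunique() != 1:
        raise ValueError("structure error: non-constant timestamp step")
    step_minutes = int(steps.iloc[0])
    series = FluxSeries(
        site_id=site_id,
        latitude=latitude,
        longitude=longitude,
        biome=biome,
        step_minutes=step_minutes,
        data=df,
    )
    return flag_day_night(series)


def gap_fill_rh(series: FluxSeries, seed: int, min_train: int = 100) -> FluxSeries:
    """Fill missing relative humidity from air temperature and VPD.

    A random-forest regression of RH on (Tair, VPD) is trained on the
    records where RH is observed and used to predict the gaps; predictions
    are clamped to [0, 100] and observed values are never touched.
    Deterministic for a fixed ``seed``.
    """
    df = series.data
    have = df["rh"].notna() & df["tair"].notna() & df["vpd"].notna()
    gaps = df["rh"].isna() & df["tair"].notna() & df["vpd"].notna()
    if not gaps.any():
        return series
    if int(have.sum()) < min_train:
        raise ValueError(f"insufficient data: need >= {min_train} records with RH present, have {int(have.sum())}")
    rf = RandomForestRegressor(n_estimators=60, min_samples_leaf=2, random_state=seed, n_jobs=1)
    rf.fit(df.loc[have, ["tair", "vpd"]].to_numpy(), df.loc[have, "rh"].to_numpy())
    pred = rf.predict(df.loc[gaps, ["tair", "vpd"]].to_numpy())
    out = series.copy()
    out.data.loc[gaps, "rh"] = np.clip(pred, 0.0, 100.0)
    return out


def flag_day_night(series: FluxSeries, sw_threshold: float = SW_DAY_THRESHOLD) -> FluxSeries:
    """Attach ``is_day = sw_in > sw_threshold`` (strict inequality, so a
    record exactly at the threshold is night). Missing sw_in raises."""
    if series.data["sw_in"].isna().any():
        raise ValueError("sw_in must be present on every record to flag day/night")
    out = series.copy()
    out.data["is_day"] = out.data["sw_in"].to_numpy() > sw_threshold
    return out


def qc_filter(series: FluxSeries, max_qc: int = 0) -> FluxSeries:
    """Mask NEE where the quality flag exceeds ``max_qc``.

    Only measured (or sufficiently trusted) NEE enters parameter fitting;
    driver columns are retained so the forward model can still predict at
    the masked steps. qc 0 = measured, higher = gap-filled.
    """
    out = series.copy()
    bad = out.data["qc_nee"] > max_qc
    out.data.loc[bad, "nee"] = np.nan
    return out
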