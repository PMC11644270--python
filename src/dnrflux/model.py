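"""DT-RH forward model: light-response GPP plus humidity-modified Lloyd-Taylor respiration.

Net ecosystem exchange (NEE, µmol C m⁻² s⁻¹, release positive) is modelled as

    NEE = -GPP(Q, VPD) + ER(Tair, RH)

where GPP follows a rectangular-hyperbola light response whose plateau β is
down-regulated above a vapour-pressure-deficit threshold, and ER is the
Lloyd-Taylor exponential in air temperature scaled by a relative-humidity
factor fh.  Daytime and nighttime respiration carry separate base rates
(R_ref) and apparent temperature sensitivities (E₀), which is the point of
the whole package: the two E₀ are estimated independently so their diel
asymmetry ΔE₀ = E₀,night/E₀,day can be measured.

The uptake sign on GPP follows the micrometeorological convention
(negative = net uptake); pass ``gpp_sign=+1`` to flip it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelConstants",
    "DayParams",
    "NightParams",
    "DriverSlice",
    "lloyd_taylor",
    "humidity_factor",
    "beta_of_vpd",
    "light_response",
    "predict_nee",
    "daytime_er",
    "DEFAULT_CONSTANTS",
]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed constants of the respiration and light-response terms.

    Parameters
    ----------
    t_ref
        Reference temperature (°C) at which respiration equals R_ref.
    t0
        Lower temperature asymptote (°C) of the Lloyd-Taylor function.
        Air temperatures must stay strictly above it.
    vpd0
        Vapour-pressure-deficit threshold (hPa) above which the light-
        saturated uptake β decays exponentially.
    """

    t_ref: float = 15.0
    t0: float = -46.02
    vpd0: float = 10.0

    def __post_init__(self) -> None:
        if not self.t0 < self.t_ref:
            raise ValueError(f"t0 ({self.t0}) must be below t_ref ({self.t_ref})")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass
class DayParams:
    """Daytime model parameters.

    alpha : canopy quantum yield (µmol C J⁻¹), initial slope of the light
        response; beta0 : light-saturated uptake at low VPD (µmol C m⁻² s⁻¹);
    k : VPD response coefficient (hPa⁻¹); r_ref_day : daytime base
        respiration at t_ref (µmol C m⁻² s⁻¹); e0_day : daytime apparent
        temperature sensitivity (K); epsilon : site-specific sign (±1) of the
        humidity modifier.
    """

    alpha: float
    beta0: float
    k: float
    r_ref_day: float
    e0_day: float
    epsilon: int = 1

    def validate(self) -> None:
        if self.alpha <= 0 or self.beta0 <= 0 or self.r_ref_day <= 0 or self.e0_day <= 0:
            raise ValueError("alpha, beta0, r_ref_day and e0_day must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.epsilon not in (-1, 1):
            raise ValueError("epsilon must be -1 or +1")


@dataclass
class NightParams:
    """Nighttime parameters: base respiration r_ref_night (µmol C m⁻² s⁻¹)
    and apparent temperature sensitivity e0_night (K)."""

    r_ref_night: float
    e0_night: float

    def validate(self) -> None:
        if self.r_ref_night <= 0 or self.e0_night <= 0:
            raise ValueError("r_ref_night and e0_night must be positive")


@dataclass
class DriverSlice:
    """Meteorological drivers for one or more half-hourly records.

    Fields may be scalars or equally-shaped arrays: global radiation q
    (W m⁻²), air temperature tair (°C), vpd (hPa), relative humidity rh (%),
    and rh_window_mean (%), the mean daytime RH of the estimation window the
    record belongs to.
    """

    q: np.ndarray | float
    tair: np.ndarray | float
    vpd: np.ndarray | float
    rh: np.ndarray | float
    rh_window_mean: np.ndarray | float


def lloyd_taylor(r_ref, e0, tair, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Lloyd-Taylor respiration R = r_ref·exp(e0·(1/(t_ref−t0) − 1/(tair−t0))).

    All temperatures in °C; e0 in K (the °C and Kelvin forms differ only by
    the constant offset absorbed in t0). Strictly increasing in tair for
    e0 > 0 and equal to r_ref at tair = t_ref.
    """
    tair = np.asarray(tair, dtype=float)
    if np.any(tair <= constants.t0):
        raise ValueError(f"air temperature must exceed t0 = {constants.t0} °C")
    expo = 1.0 / (constants.t_ref - constants.t0) - 1.0 / (tair - constants.t0)
    return r_ref * np.exp(np.asarray(e0, dtype=float) * expo)


def humidity_factor(epsilon, rh, rh_window_mean):
    """Relative-humidity modifier fh = 1 − ε·(RH − RH̄)/RH̄, floored at 0.

    ε = +1 encodes respiration suppressed under humid (wet-ecosystem)
    conditions, ε = −1 the opposite. fh = 1 when RH equals the window mean.
    The floor guards against negative respiration when ε = +1 and
    RH > 2·RH̄; such clipping is logged once per call.
    """
    rh_window_mean = np.asarray(rh_window_mean, dtype=float)
    if np.any(rh_window_mean <= 0):
        raise ValueError("rh_window_mean must be positive")
    fh = 1.0 - epsilon * (np.asarray(rh, dtype=float) - rh_window_mean) / rh_window_mean
    if np.any(fh < 0):
        warnings.warn("humidity factor clipped at 0 (RH far above window mean)", stacklevel=2)
        fh = np.maximum(fh, 0.0)
    return fh


def beta_of_vpd(beta0, k, vpd, constants: ModelConstants = DEFAULT_CONSTANTS):
    """VPD-limited light-saturated uptake: β = β₀·exp(−k·(VPD−VPD₀)) above
    VPD₀, β₀ below; continuous at the threshold and non-increasing in VPD."""
    vpd = np.asarray(vpd, dtype=float)
    return np.where(vpd > constants.vpd0, beta0 * np.exp(-k * (vpd - constants.vpd0)), beta0)


def light_response(alpha, beta, q):
    """Rectangular-hyperbola GPP: α·β·Q/(α·Q + β); 0 at Q = 0, asymptote β."""
    q = np.asarray(q, dtype=float)
    denom = alpha * q + beta
    return np.where(denom > 0, alpha * beta * q / denom, 0.0)


def predict_nee(
    day_params: DayParams,
    night_params: NightParams,
    drivers: DriverSlice,
    is_day,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    gpp_sign: int = -1,
    use_fh: bool = True,
):
    """Model NEE for a slice of records.

    Daytime: NEE = gpp_sign·GPP + R_day·fh with the five daytime parameters;
    nighttime: NEE = R_night with the two nighttime parameters (the humidity
    modifier applies to the daytime fit only, keeping the nighttime model at
    two parameters). Vectorized over records; ``is_day`` may be a boolean
    array aligned with the drivers.
    """
    is_day = np.asarray(is_day, dtype=bool)
    tair = np.asarray(drivers.tair, dtype=float)
    night_er = lloyd_taylor(night_params.r_ref_night, night_params.e0_night, tair, constants)
    day_er = lloyd_taylor(day_params.r_ref_day, day_params.e0_day, tair, constants)
    if use_fh:
        day_er = day_er * humidity_factor(day_params.epsilon, drivers.rh, drivers.rh_window_mean)
    beta = beta_of_vpd(day_params.beta0, day_params.k, drivers.vpd, constants)
    gpp = light_response(day_params.alpha, beta, drivers.q)
    day_nee = gpp_sign * gpp + day_er
    return np.where(is_day, day_nee, night_er)


def daytime_er(
    day_params: DayParams,
    drivers: DriverSlice,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    use_fh: bool = True,
):
    """Daytime ecosystem respiration: the Lloyd-Taylor term of the daytime
    parameter set times the humidity factor (radiation plays no role)."""
    er = lloyd_taylor(day_params.r_ref_day, day_params.e0_day, drivers.tair, constants)
    if use_fh:
        er = er * humidity_factor(day_params.epsilon, drivers.rh, drivers.rh_window_mean)
    return er
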