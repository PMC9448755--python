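"""Bioclimatic predictors of forager population density.

Ten climatic summaries derived from 12 monthly mean temperatures (°C) and 12
monthly precipitation totals (mm/month):

========  ==========================================================  ==============
acronym   definition                                                  units
========  ==========================================================  ==============
ET        effective temperature, (18·MWM − 10·MCM)/(MWM − MCM + 8)    °C
PET       Thornthwaite annual potential evapotranspiration            mm/yr
NPP       Miami-model net primary productivity                        g·m⁻²·yr⁻¹
MCM       mean temperature of the coldest month                      °C
MWM       mean temperature of the warmest month                      °C
TS        temperature seasonality (population sd of monthly means)    °C
TAP       log10 total annual precipitation                            log10 mm/yr
PDM       log10 precipitation of the driest month                     log10 mm/month
PWM       log10 precipitation of the wettest month                    log10 mm/month
PSeason   precipitation seasonality, 100·sd/mean of monthly totals    dimensionless
========  ==========================================================  ==============

ET condenses the annual thermal regime into one number: it equals the annual
mean in a seasonless climate and is pulled towards the warm-month mean as
seasonality grows.  The Miami model takes the *minimum* of a temperature- and
a precipitation-limited productivity term with a 3000 g·m⁻²·yr⁻¹ ceiling —
itself a Liebig-style construction.  Precipitation variables are log10(x + 1)
by default so that fully dry months are admissible; TS uses the population
(divisor-12) standard deviation in plain °C, and PSeason is the percent
coefficient of variation of the monthly totals.

All functions accept scalars or numpy arrays broadcast over trailing axes;
the month axis is always axis 0 of a (12, ...) stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np

#: Canonical variable order; also the tie-breaking order for Liebig argmin.
VARIABLE_ORDER: tuple[str, ...] = (
    "ET", "PET", "NPP", "MCM", "MWM", "TS", "TAP", "PDM", "PWM", "PSeason",
)

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)
# mid-month day of year, used for the solar declination of each month
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349], float)


@dataclass(frozen=True)
class MonthlyClimate:
    """Twelve monthly mean temperatures (°C) and precipitation totals (mm)."""

    t_monthly: np.ndarray
    p_monthly: np.ndarray
    lat: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.t_monthly, float)
        p = np.asarray(self.p_monthly, float)
        if t.shape != (12,) or p.shape != (12,):
            raise ValueError("t_monthly and p_monthly must each have 12 entries")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ValueError("monthly climate values must be finite")
        if np.any(p < 0):
            raise ValueError("monthly precipitation must be non-negative")
        object.__setattr__(self, "t_monthly", t)
        object.__setattr__(self, "p_monthly", p)


@dataclass(frozen=True)
class PredictorVector:
    """The ten predictors for one location, keyed by :data:`VARIABLE_ORDER`."""

    ET: float
    PET: float
    NPP: float
    MCM: float
    MWM: float
    TS: float
    TAP: float
    PDM: float
    PWM: float
    PSeason: float

    def get(self, variable_id: str) -> float:
        if variable_id not in VARIABLE_ORDER:
            raise KeyError(f"unknown predictor {variable_id!r}")
        return getattr(self, variable_id)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class PredictorConfig:
    """Conventions behind PET/NPP/precipitation transforms.

    carbon_factor scales Miami NPP from dry matter towards carbon
    (0.45–0.5 for a strict carbon accounting; 1.0 keeps the classic
    3000 g·m⁻²·yr⁻¹ ceiling).  precip_log_offset is the +1 mm admitting
    zero months in the log10 transforms; set 0.0 to disable.
    """

    carbon_factor: float = 1.0
    precip_log_offset: float = 1.0
    pet_method: str = "thornthwaite"


DEFAULT_PREDICTOR_CONFIG = PredictorConfig()


def effective_temperature(mwm, mcm):
    """Effective temperature ET = (18·MWM − 10·MCM)/(MWM − MCM + 8), in °C.

    Requires MWM − MCM + 8 > 0 (always true when MWM ≥ MCM).
    """
    mwm = np.asarray(mwm, float)
    mcm = np.asarray(mcm, float)
    denom = mwm - mcm + 8.0
    if np.any(denom <= 0):
        raise ValueError("effective temperature undefined: MWM - MCM + 8 <= 0")
    out = (18.0 * mwm - 10.0 * mcm) / denom
    return out if out.ndim else float(out)


def _day_length_hours(lat_deg, doy):
    """Daylight hours from latitude and day of year (spherical sunset angle)."""
    lat = np.deg2rad(np.asarray(lat_deg, float))
    decl = np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (np.asarray(doy, float) + 10.0) / 365.0))
    cos_omega = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


def potential_evapotranspiration(t_monthly, lat=0.0):
    """Annual Thornthwaite PET (mm/yr) with the standard day-length correction.

    Monthly PET = 16·(L/12)·(N/30)·(10·T/I)^a for 0 < T ≤ 26.5 °C, with the
    quadratic hot-month branch above 26.5 °C; months at or below freezing
    contribute nothing.  I is the annual heat index Σ(T/5)^1.514 over months
    with T > 0 and a its cubic polynomial.
    """
    t = np.asarray(t_monthly, float)
    if t.shape[0] != 12:
        raise ValueError("expected month axis of length 12 on axis 0")
    lat = np.broadcast_to(np.asarray(lat, float), t.shape[1:])

    warm = t > 0.0
    heat_index = np.sum(np.where(warm, (np.maximum(t, 0.0) / 5.0) ** 1.514, 0.0), axis=0)
    a = (6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2
         + 1.7912e-2 * heat_index + 0.49239)

    with np.errstate(divide="ignore", invalid="ignore"):
        base = 16.0 * (10.0 * np.maximum(t, 0.0) / np.where(heat_index > 0, heat_index, np.nan)) ** a
    hot = t > 26.5
    base = np.where(hot, -415.85 + 32.24 * t - 0.43 * t**2, base)
    base = np.where(warm & (heat_index > 0), base, 0.0)
    base = np.nan_to_num(base, nan=0.0)

    daylen = _day_length_hours(lat[np.newaxis, ...] if lat.ndim else lat,
                               _MID_MONTH_DOY.reshape((12,) + (1,) * np.ndim(lat)))
    corr = (daylen / 12.0) * (_DAYS_IN_MONTH.reshape((12,) + (1,) * np.ndim(lat)) / 30.0)
    out = np.sum(base * corr, axis=0)
    return out if out.ndim else float(out)


def npp_miami(mat, tap_mm, carbon_factor: float = 1.0):
    """Miami-model NPP: min of temperature- and precipitation-limited terms.

    NPP = min(3000/(1+e^(1.315−0.119·T)), 3000·(1−e^(−0.000664·P))) scaled by
    ``carbon_factor``; T is mean annual temperature (°C), P annual
    precipitation (mm/yr ≥ 0).
    """
    mat = np.asarray(mat, float)
    tap_mm = np.asarray(tap_mm, float)
    if np.any(tap_mm < 0):
        raise ValueError("annual precipitation must be non-negative")
    npp_t = 3000.0 / (1.0 + np.exp(1.315 - 0.119 * mat))
    npp_p = 3000.0 * (1.0 - np.exp(-0.000664 * tap_mm))
    out = carbon_factor * np.minimum(npp_t, npp_p)
    return out if out.ndim else float(out)


def _population_sd(x, axis=0):
    return np.std(np.asarray(x, float), axis=axis, ddof=0)


def derive_predictor_arrays(t_monthly, p_monthly, lat,
                            cfg: PredictorConfig = DEFAULT_PREDICTOR_CONFIG
                            ) -> dict[str, np.ndarray]:
    """Vectorized predictor derivation over (12, ...) monthly stacks."""
    t = np.asarray(t_monthly, float)
    p = np.asarray(p_monthly, float)
    if t.shape[0] != 12 or p.shape[0] != 12:
        raise ValueError("month axis of length 12 expected on axis 0")
    if np.any(p < 0):
        raise ValueError("monthly precipitation must be non-negative")

    mcm = t.min(axis=0)
    mwm = t.max(axis=0)
    ts = _population_sd(t, axis=0)
    annual_p = p.sum(axis=0)
    mat = t.mean(axis=0)
    off = cfg.precip_log_offset

    pm_mean = p.mean(axis=0)
    pm_sd = _population_sd(p, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pseason = np.where(pm_mean > 0, 100.0 * pm_sd / pm_mean, 0.0)

    return {
        "ET": np.asarray(effective_temperature(mwm, mcm)),
        "PET": np.asarray(potential_evapotranspiration(t, lat)),
        "NPP": np.asarray(npp_miami(mat, annual_p, cfg.carbon_factor)),
        "MCM": mcm,
        "MWM": mwm,
        "TS": ts,
        "TAP": np.log10(annual_p + off),
        "PDM": np.log10(p.min(axis=0) + off),
        "PWM": np.log10(p.max(axis=0) + off),
        "PSeason": pseason,
    }


def derive_predictors(mc: MonthlyClimate,
                      cfg: PredictorConfig = DEFAULT_PREDICTOR_CONFIG) -> PredictorVector:
    """Derive the ten-variable :class:`PredictorVector` for one location."""
    arrays = derive_predictor_arrays(mc.t_monthly, mc.p_monthly, mc.lat, cfg)
    return PredictorVector(**{k: float(v) for k, v in arrays.items()})
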