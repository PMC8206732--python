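"""Stochastic daily weather generation and climate-scenario perturbation.

The generator produces season-spanning daily series (Tmin, Tmax, rain, global
radiation) with the statistical structure a site's monthly climatology
implies:

* precipitation occurrence follows a monthly first-order two-state Markov
  chain; wet-day amounts are gamma distributed with a monthly mean and a
  shape parameter shared across months;
* daily mean temperature is the monthly normal plus an AR(1) residual with a
  stationary standard deviation ``temp_sd`` and lag-1 autocorrelation
  ``temp_ar1``; Tmax/Tmin are the mean plus/minus half the diurnal range,
  with a Tmax depression on wet days;
* global radiation is a clearness fraction times extraterrestrial radiation
  at the site latitude, reduced by a fixed factor on wet days.

Future climates are represented by change factors: additive monthly
temperature deltas, multiplicative monthly precipitation and radiation
factors, and a scenario CO2 concentration. A synthetic multi-member GCM-like
ensemble with configurable inter-member spread stands in for downscaled
climate-model projections.

All years are non-leap (365 days) to keep day-of-year arithmetic simple.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .solar import extraterrestrial_radiation

__all__ = [
    "MONTH_LENGTHS",
    "month_of_doy",
    "DailyWeather",
    "WeatherSeries",
    "SiteClimate",
    "ClimateScenario",
    "ScenarioSpread",
    "BASELINE_CO2_PPM",
    "RCP_CO2_PPM",
    "apply_scenario",
    "generate_weather",
    "make_gcm_ensemble",
    "markov_stationary_wet_fraction",
]

# 365-day calendar (non-leap), used throughout the package.
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_OF_DOY = np.repeat(np.arange(12), MONTH_LENGTHS)  # 0-based month per doy-1

#: CO2 concentration (ppm) of the 1981-2010 baseline climate.
BASELINE_CO2_PPM = 363.8

#: 2050 CO2 concentrations (ppm) by representative concentration pathway.
RCP_CO2_PPM = {"RCP4.5": 487.0, "RCP8.5": 541.0}

#: First day of a generated season series: 1 October, safely before sowing.
SEASON_START_DOY = 274
#: Last day of a generated season series: 31 August of the harvest year.
SEASON_END_DOY = 243


def month_of_doy(doy):
    """0-based calendar month for a day of year (1-365)."""
    d = np.asarray(doy)
    if np.any((d < 1) | (d > 365)):
        raise ValueError("day of year must be in 1..365")
    out = _MONTH_OF_DOY[d - 1]
    return int(out) if np.isscalar(doy) else out


def _as_monthly(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape == ():
        arr = np.full(12, float(arr))
    if arr.shape != (12,):
        raise ValueError(f"{name} must be a scalar or length-12 sequence, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class DailyWeather:
    """One day's weather record."""

    day_of_year: int
    tmin: float
    tmax: float
    rain: float
    srad: float

    def __post_init__(self):
        if not 1 <= self.day_of_year <= 366:
            raise ValueError(f"day_of_year {self.day_of_year} outside 1..366")
        if self.tmin > self.tmax:
            raise ValueError(f"tmin {self.tmin} > tmax {self.tmax}")
        if self.rain < 0:
            raise ValueError("rain must be non-negative")
        if self.srad < 0:
            raise ValueError("srad must be non-negative")


@dataclass
class WeatherSeries:
    """A consecutive run of daily weather for one site and harvest year.

    Data are stored as parallel numpy arrays; iterate to obtain
    :class:`DailyWeather` records. The series must cover consecutive calendar
    days (wrapping 365 -> 1 at new year) with no gaps.
    """

    site_id: str
    harvest_year: int
    doy: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray
    srad: np.ndarray

    def __post_init__(self):
        self.doy = np.asarray(self.doy, dtype=int)
        for name in ("tmin", "tmax", "rain", "srad"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.doy)
        if n == 0:
            raise ValueError("weather series is empty")
        for name in ("tmin", "tmax", "rain", "srad"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} has length mismatch")
        steps = np.diff(self.doy)
        ok = (steps == 1) | ((self.doy[:-1] == 365) & (self.doy[1:] == 1))
        if not np.all(ok):
            i = int(np.argmin(ok))
            raise ValueError(
                f"non-consecutive days at position {i}: doy {self.doy[i]} -> {self.doy[i + 1]}"
            )
        if np.any(self.tmin > self.tmax):
            i = int(np.argmax(self.tmin > self.tmax))
            raise ValueError(f"tmin > tmax at position {i} (doy {self.doy[i]})")
        if np.any(self.rain < 0) or np.any(self.srad < 0):
            raise ValueError("rain and srad must be non-negative")

    def __len__(self) -> int:
        return len(self.doy)

    def __iter__(self) -> Iterator[DailyWeather]:
        for i in range(len(self)):
            yield DailyWeather(
                int(self.doy[i]),
                float(self.tmin[i]),
                float(self.tmax[i]),
                float(self.rain[i]),
                float(self.srad[i]),
            )

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)

    def to_frame(self):
        """Tabular view with the weather-CSV column layout."""
        import pandas as pd

        return pd.DataFrame(
            {
                "site": self.site_id,
                "year": self.harvest_year,
                "doy": self.doy,
                "tmin": self.tmin,
                "tmax": self.tmax,
                "rain": self.rain,
                "srad": self.srad,
            }
        )


@dataclass
class SiteClimate:
    """Monthly climatology driving the weather generator at one site.

    Monthly fields may be given as scalars (applied to every month) or as
    length-12 sequences (January first).
    """

    site_id: str
    latitude: float
    monthly_tmean: np.ndarray
    monthly_trange: np.ndarray
    temp_sd: float = 2.0
    temp_ar1: float = 0.7
    p_wet_given_dry: np.ndarray = 0.3
    p_wet_given_wet: np.ndarray = 0.6
    gamma_shape: float = 0.75
    gamma_mean_wet: np.ndarray = 5.0
    srad_clearness: float = 0.45
    wet_day_temp_offset: float = 1.5
    wet_day_srad_factor: float = 0.6
    monthly_srad_factor: np.ndarray = 1.0

    def __post_init__(self):
        if abs(self.latitude) >= 66.5:
            raise ValueError("latitude outside supported range (|lat| < 66.5)")
        for name in (
            "monthly_tmean",
            "monthly_trange",
            "p_wet_given_dry",
            "p_wet_given_wet",
            "gamma_mean_wet",
            "monthly_srad_factor",
        ):
            setattr(self, name, _as_monthly(name, getattr(self, name)))
        if np.any(self.monthly_trange < 0):
            raise ValueError("monthly_trange must be non-negative")
        for name in ("p_wet_given_dry", "p_wet_given_wet"):
            p = getattr(self, name)
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.temp_ar1 < 1:
            raise ValueError("temp_ar1 must lie in [0, 1)")
        if self.temp_sd < 0:
            raise ValueError("temp_sd must be non-negative")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if np.any(self.gamma_mean_wet < 0):
            raise ValueError("gamma_mean_wet must be non-negative")
        if not 0 < self.srad_clearness <= 1:
            raise ValueError("srad_clearness must lie in (0, 1]")
        if not 0 < self.wet_day_srad_factor <= 1:
            raise ValueError("wet_day_srad_factor must lie in (0, 1]")
        if np.any(self.monthly_srad_factor <= 0):
            raise ValueError("monthly_srad_factor must be positive")


@dataclass
class ClimateScenario:
    """A CO2 concentration plus monthly change factors for one projection."""

    label: str
    co2_ppm: float
    delta_tmean: np.ndarray = 0.0
    precip_factor: np.ndarray = 1.0
    srad_factor: np.ndarray = 1.0

    def __post_init__(self):
        if self.co2_ppm <= 0:
            raise ValueError("co2_ppm must be positive")
        self.delta_tmean = _as_monthly("delta_tmean", self.delta_tmean)
        self.precip_factor = _as_monthly("precip_factor", self.precip_factor)
        self.srad_factor = _as_monthly("srad_factor", self.srad_factor)
        if np.any(self.precip_factor < 0):
            raise ValueError("precip_factor must be non-negative")
        if np.any(self.srad_factor <= 0):
            raise ValueError("srad_factor must be positive")

    @classmethod
    def baseline(cls) -> "ClimateScenario":
        """The 1981-2010 baseline: 363.8 ppm CO2, no perturbation."""
        return cls(label="baseline", co2_ppm=BASELINE_CO2_PPM)


def apply_scenario(base: SiteClimate, scenario: ClimateScenario) -> SiteClimate:
    """Perturb a site climatology by a scenario's change factors.

    Temperature deltas add to the monthly means; precipitation factors scale
    the mean wet-day amounts; radiation factors scale the effective monthly
    clearness. Every other statistic is untouched and the input is not
    modified.
    """
    return replace(
        base,
        monthly_tmean=base.monthly_tmean + scenario.delta_tmean,
        gamma_mean_wet=base.gamma_mean_wet * scenario.precip_factor,
        monthly_srad_factor=base.monthly_srad_factor * scenario.srad_factor,
    )


def markov_stationary_wet_fraction(p_wet_given_dry: float, p_wet_given_wet: float) -> float:
    """Long-run wet-day fraction of the two-state occurrence chain."""
    denom = 1.0 + p_wet_given_dry - p_wet_given_wet
    if denom <= 0:
        return 1.0
    return p_wet_given_dry / denom


def _season_doys() -> np.ndarray:
    return np.concatenate(
        [np.arange(SEASON_START_DOY, 366), np.arange(1, SEASON_END_DOY + 1)]
    )


def _generate_series(
    climate: SiteClimate, rng: np.random.Generator, harvest_year: int
) -> WeatherSeries:
    doys = _season_doys()
    n = len(doys)
    months = month_of_doy(doys)

    # Precipitation occurrence: monthly first-order Markov chain.
    p_wd = climate.p_wet_given_dry
    p_ww = climate.p_wet_given_wet
    u = rng.random(n)
    wet = np.empty(n, dtype=bool)
    m0 = months[0]
    wet[0] = u[0] < markov_stationary_wet_fraction(p_wd[m0], p_ww[m0])
    for i in range(1, n):
        m = months[i]
        p = p_ww[m] if wet[i - 1] else p_wd[m]
        wet[i] = u[i] < p

    # Wet-day amounts: gamma with monthly mean, shared shape.
    rain = np.zeros(n)
    if wet.any():
        scale = climate.gamma_mean_wet[months[wet]] / climate.gamma_shape
        rain[wet] = rng.gamma(climate.gamma_shape, scale)

    # AR(1) residual with stationary sd temp_sd.
    rho = climate.temp_ar1
    innov_sd = climate.temp_sd * np.sqrt(1.0 - rho * rho)
    z = rng.normal(0.0, 1.0, n)
    e = np.empty(n)
    e[0] = climate.temp_sd * z[0]
    for i in range(1, n):
        e[i] = rho * e[i - 1] + innov_sd * z[i]

    tmean = climate.monthly_tmean[months] + e
    half_range = 0.5 * climate.monthly_trange[months]
    tmin = tmean - half_range
    tmax = tmean + half_range - np.where(wet, climate.wet_day_temp_offset, 0.0)
    tmax = np.maximum(tmax, tmin)

    ra = extraterrestrial_radiation(climate.latitude, doys)
    srad = climate.srad_clearness * climate.monthly_srad_factor[months] * ra
    srad = srad * np.where(wet, climate.wet_day_srad_factor, 1.0)
    srad = np.maximum(srad, 0.0)

    return WeatherSeries(
        site_id=climate.site_id,
        harvest_year=harvest_year,
        doy=doys,
        tmin=tmin,
        tmax=tmax,
        rain=rain,
        srad=srad,
    )


def generate_weather(
    climate: SiteClimate,
    n_years: int,
    seed,
    first_harvest_year: int = 2001,
) -> list[WeatherSeries]:
    """Generate ``n_years`` independent season-spanning weather series.

    Each series runs from 1 October of the preceding calendar year through
    31 August of the harvest year (335 days on the non-leap calendar),
    covering a 20 October sowing through harvest. Each year draws from its
    own RNG stream spawned deterministically from ``seed``, so output is
    bitwise reproducible and independent of evaluation order.
    """
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n_years)
    return [
        _generate_series(climate, np.random.default_rng(children[i]), first_harvest_year + i)
        for i in range(n_years)
    ]


@dataclass(frozen=True)
class ScenarioSpread:
    """Inter-member spread of a synthetic GCM-like scenario ensemble.

    Each pair is (ensemble mean, inter-member standard deviation) of a
    winter (January) or summer (July) anchor value; monthly values follow a
    cosine seasonal interpolation between the two anchors.
    """

    dtemp_winter: tuple[float, float]
    dtemp_summer: tuple[float, float]
    precip_winter: tuple[float, float]
    precip_summer: tuple[float, float]
    srad_winter: tuple[float, float] = (1.0, 0.0)
    srad_summer: tuple[float, float] = (1.0, 0.0)


#: Default 2050-like spreads: warmer throughout with stronger summer warming,
#: slightly wetter winters, drier summers, and a small seasonal radiation
#: adjustment mirroring the cloud-cover response.
DEFAULT_SPREADS = {
    "RCP4.5": ScenarioSpread(
        dtemp_winter=(1.6, 0.4),
        dtemp_summer=(2.0, 0.5),
        precip_winter=(1.05, 0.05),
        precip_summer=(0.85, 0.08),
        srad_winter=(0.98, 0.02),
        srad_summer=(1.02, 0.02),
    ),
    "RCP8.5": ScenarioSpread(
        dtemp_winter=(2.2, 0.5),
        dtemp_summer=(2.8, 0.6),
        precip_winter=(1.08, 0.06),
        precip_summer=(0.78, 0.10),
        srad_winter=(0.97, 0.02),
        srad_summer=(1.03, 0.02),
    ),
}

# Seasonal weight: 0 in January rising to 1 in July and back (cosine shape).
_SUMMER_WEIGHT = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(12) / 12.0))


def make_gcm_ensemble(
    n_members: int,
    rcp: str,
    seed,
    spread_spec: ScenarioSpread | None = None,
) -> list[ClimateScenario]:
    """Draw a synthetic ensemble of GCM-like 2050 scenarios for one pathway.

    All members share the pathway's CO2 concentration (487 ppm for RCP4.5,
    541 ppm for RCP8.5) but have member-specific monthly temperature deltas
    and precipitation/radiation factors drawn around the ensemble-mean
    seasonal anchors of ``spread_spec``. With zero spread every member equals
    the ensemble mean. Fully reproducible for a fixed seed.
    """
    if n_members < 1:
        raise ValueError("n_members must be at least 1")
    if rcp not in RCP_CO2_PPM:
        raise ValueError(f"unknown RCP label {rcp!r}; expected one of {sorted(RCP_CO2_PPM)}")
    spec = spread_spec if spread_spec is not None else DEFAULT_SPREADS[rcp]
    co2 = RCP_CO2_PPM[rcp]
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    members = []
    for i in range(n_members):
        tw = rng.normal(*spec.dtemp_winter)
        ts = rng.normal(*spec.dtemp_summer)
        pw = rng.normal(*spec.precip_winter)
        ps = rng.normal(*spec.precip_summer)
        sw = rng.normal(*spec.srad_winter)
        ss = rng.normal(*spec.srad_summer)
        delta_t = tw + (ts - tw) * _SUMMER_WEIGHT
        pf = np.clip(pw + (ps - pw) * _SUMMER_WEIGHT, 0.0, None)
        sf = np.clip(sw + (ss - sw) * _SUMMER_WEIGHT, 0.05, None)
        members.append(
            ClimateScenario(
                label=f"GCM{i + 1:02d}-{rcp}",
                co2_ppm=co2,
                delta_tmean=delta_t,
                precip_factor=pf,
                srad_factor=sf,
            )
        )
    return members
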