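"""Daily-timestep winter-wheat simulator.

A deliberately compact process-based model in the tradition of thermal-time
wheat simulators: phenology driven by thermal time, vernalization and
photoperiod; canopy light interception by Beer's law; biomass as intercepted
PAR times a radiation-use efficiency (RUE) with a linear CO2 response; a
layered bucket soil-water balance (5-cm layers) with a piecewise-linear
moisture "choking" function that throttles RUE, soil evaporation and canopy
senescence; and grain-yield decomposition into ear mass at flowering, grain
number per unit ear mass, and single-grain weight.

Two distinct stress pathways affect yield:

* *source-capacity* stress — seasonal water limitation reduces daily
  assimilation and accelerates senescence (the water stress index pathway);
* *sink-capacity* stress — drought or heat in a short window around anthesis
  reduces fertile grain number, capping the grain mass a season can fill
  (the drought/heat stress index pathway). Cultivar flags switch these
  sensitivities on or off, which is how the four-yield experimental design
  (potential, water-limited tolerant, drought-sensitive, heat-sensitive)
  is realized.

Units: biomass in g m-2 (1 t ha-1 = 100 g m-2), water in mm, thermal time in
degree-days. Yields are dry matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .solar import daylength
from .weather import WeatherSeries

__all__ = [
    "CultivarParams",
    "SoilProfile",
    "SeasonResult",
    "CultivarSetResult",
    "SOWING_DOY_DEFAULT",
    "thermal_time_increment",
    "co2_rue_factor",
    "water_stress_factor",
    "potential_et",
    "soil_water_update",
    "vernalization_effectiveness",
    "grain_set_factor",
    "run_season",
    "run_cultivar_set",
]

#: Default sowing date, 20 October (day of year on the non-leap calendar).
SOWING_DOY_DEFAULT = 293

#: Reference CO2 concentration (ppm) of the linear RUE fertilization rule.
CO2_REFERENCE_PPM = 364.0


@dataclass(frozen=True)
class CultivarParams:
    """Cultivar parameterization.

    Defaults describe a vernalization-requiring British winter wheat with a
    moderate-to-weak daylength response, loosely calibrated so water-limited
    GB yields fall in the 8-12 t/ha range. The two sensitivity flags select
    whether grain set responds to drought or heat around flowering.
    """

    name: str = "winter-wheat"
    t_base: float = 0.0                  # deg C, thermal-time base
    phyllochron: float = 100.0           # deg C d per leaf
    min_leaf_number: float = 8.0
    max_leaf_number: float = 14.0
    vern_full: float = 40.0              # vernal-days for full vernalization
    vern_t_min: float = -4.0             # deg C, below: no vernalizing effect
    vern_t_opt_lo: float = 0.0           # deg C, plateau of full effectiveness
    vern_t_opt_hi: float = 12.0
    vern_t_max: float = 16.0             # deg C, above: no vernalizing effect
    photoperiod_sens: float = 0.75       # development-rate reduction strength
    daylength_saturation: float = 15.0   # h; no photoperiod limitation above
    rue: float = 2.2                     # g DM per MJ intercepted PAR
    k_ext: float = 0.45                  # canopy extinction coefficient
    lai_max: float = 6.5                 # canopy cap, m2 m-2
    grains_per_ear_mass: float = 100.0   # grains per g ear dry mass
    potential_grain_weight: float = 45.0  # mg per grain
    ear_partition: float = 0.25          # ear fraction of biomass at anthesis
    remobilization_frac: float = 0.35    # stem reserves transferable to grain
    grain_fill_duration: float = 650.0   # deg C d anthesis -> maturity
    emergence_tt: float = 150.0          # deg C d sowing -> emergence
    temp_response_range: float = 10.0    # deg C, ramp width of f_T above t_base
    root_growth_rate: float = 1.0        # mm rooting depth per deg C d
    drought_sensitive: bool = False
    heat_sensitive: bool = False
    heat_threshold: float = 27.0         # deg C tmax triggering floret damage
    stress_window: int = 5               # days each side of anthesis
    drought_slope: float = 1.0           # grain-set loss per unit mean stress
    heat_slope: float = 0.05             # grain-set loss per deg C d above threshold
    grain_set_floor: float = 0.2
    choking_threshold: float = 0.5       # FTSW below which choking starts
    senescence_stress_accel: float = 2.0

    def __post_init__(self):
        positive = (
            "phyllochron", "min_leaf_number", "max_leaf_number", "vern_full",
            "rue", "k_ext", "lai_max", "grains_per_ear_mass",
            "potential_grain_weight", "ear_partition", "grain_fill_duration",
            "emergence_tt", "temp_response_range",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_leaf_number > self.max_leaf_number:
            raise ValueError("min_leaf_number must not exceed max_leaf_number")
        if not (self.vern_t_min <= self.vern_t_opt_lo <= self.vern_t_opt_hi <= self.vern_t_max):
            raise ValueError("vernalization temperatures must be ordered")
        if self.photoperiod_sens < 0:
            raise ValueError("photoperiod_sens must be non-negative")
        if not 0 < self.choking_threshold <= 1:
            raise ValueError("choking_threshold must lie in (0, 1]")
        if not 0 <= self.grain_set_floor <= 1:
            raise ValueError("grain_set_floor must lie in [0, 1]")


@dataclass(frozen=True)
class SoilProfile:
    """A uniform stack of 5-cm soil layers characterized by total AWC.

    The default is a medium available-water-capacity profile (AWC = 177 mm
    over 150 cm) assumed full at sowing, matching typical autumn conditions.
    """

    awc_total: float = 177.0   # mm plant-available water over the profile
    n_layers: int = 30         # 5-cm layers (30 -> 150 cm rooting depth)
    evap_layer_depth: float = 10.0  # cm subject to soil evaporation
    initial_fill: float = 1.0

    LAYER_THICKNESS_CM: float = 5.0

    def __post_init__(self):
        if self.awc_total <= 0:
            raise ValueError("awc_total must be positive")
        if self.n_layers < 1:
            raise ValueError("n_layers must be at least 1")
        if not 0 <= self.initial_fill <= 1:
            raise ValueError("initial_fill must lie in [0, 1]")
        if self.evap_layer_depth <= 0:
            raise ValueError("evap_layer_depth must be positive")

    @property
    def layer_capacity(self) -> float:
        """Plant-available capacity per 5-cm layer (mm)."""
        return self.awc_total / self.n_layers

    @property
    def depth_mm(self) -> float:
        return self.n_layers * self.LAYER_THICKNESS_CM * 10.0

    @property
    def n_evap_layers(self) -> int:
        return max(1, min(self.n_layers, math.ceil(self.evap_layer_depth / self.LAYER_THICKNESS_CM)))


@dataclass
class SeasonResult:
    """Outcome and seasonal diagnostics of one simulated season."""

    yield_t_ha: float
    anthesis_doy: int | None
    maturity_doy: int | None
    season_et: float          # mm, cumulative evapotranspiration sowing->maturity
    swd_anthesis: float       # mm, soil water deficit at anthesis
    temp_sum: float           # deg C d sowing->maturity
    rain_total: float         # mm sowing->maturity
    intercepted_rad: float    # MJ m-2 cumulative intercepted PAR
    biomass: float            # g m-2 above-ground at maturity
    grain_number: float       # grains m-2
    failed: bool = False
    failure_reason: str = ""
    water_balance_error: float = 0.0  # max |daily closure residual| (mm)


@dataclass
class CultivarSetResult:
    """The four-yield experimental design run on one season's weather.

    yp: potential yield (stress-tolerant cultivar, water limitation off);
    yw: water-limited yield of the tolerant cultivar; ywd / ywh:
    water-limited yields of the drought- / heat-sensitive cultivars.
    ``diagnostics`` are those of the tolerant water-limited run.
    """

    yp: float
    yw: float
    ywd: float
    ywh: float
    diagnostics: SeasonResult
    failed: bool = False


def thermal_time_increment(tmin: float, tmax: float, t_base: float) -> float:
    """Daily thermal time: mean temperature above base, floored at zero."""
    if tmin > tmax:
        raise ValueError("tmin must not exceed tmax")
    return max(0.0, 0.5 * (tmin + tmax) - t_base)


def co2_rue_factor(co2_ppm: float) -> float:
    """Linear CO2 fertilization of RUE: +30% for doubling from 364 ppm."""
    if co2_ppm <= 0:
        raise ValueError("co2_ppm must be positive")
    return 1.0 + 0.30 * (co2_ppm - CO2_REFERENCE_PPM) / CO2_REFERENCE_PPM


def water_stress_factor(ftsw: float, threshold: float = 0.5) -> float:
    """Moisture choking function of the fraction of transpirable soil water.

    Unity above the threshold, declining linearly to zero at an empty
    profile. Applied multiplicatively to RUE, transpiration demand, soil
    evaporation and (inverted) to senescence rate.
    """
    if not 0.0 <= ftsw <= 1.0 + 1e-12:
        raise ValueError("ftsw must lie in [0, 1]")
    if ftsw >= threshold:
        return 1.0
    return ftsw / threshold


_PSYCHROMETRIC = 0.066   # kPa per deg C
_LATENT_HEAT = 2.45      # MJ per kg water
_PT_ALPHA = 1.26
_NET_RADIATION_FRAC = 0.6


def svp_slope(tmean: float) -> float:
    """Slope of the saturation vapour pressure curve (kPa per deg C)."""
    es = 0.6108 * math.exp(17.27 * tmean / (tmean + 237.3))
    return 4098.0 * es / (tmean + 237.3) ** 2


def potential_et(srad: float, tmean: float) -> float:
    """Priestley-Taylor-type potential evapotranspiration (mm per day).

    Net radiation is approximated as a fixed fraction of global radiation;
    the result is proportional to radiation at fixed temperature.
    """
    if srad < 0:
        raise ValueError("srad must be non-negative")
    s = svp_slope(tmean)
    rn = _NET_RADIATION_FRAC * srad
    return max(0.0, _PT_ALPHA * s / (s + _PSYCHROMETRIC) * rn / _LATENT_HEAT)


def vernalization_effectiveness(tmean: float, cv: CultivarParams) -> float:
    """Vernal-day contribution of one day at a given mean temperature.

    Full effectiveness on a temperature plateau, declining linearly to zero
    at the cold and warm bounds (trapezoidal response).
    """
    if tmean <= cv.vern_t_min or tmean >= cv.vern_t_max:
        return 0.0
    if tmean < cv.vern_t_opt_lo:
        return (tmean - cv.vern_t_min) / (cv.vern_t_opt_lo - cv.vern_t_min)
    if tmean > cv.vern_t_opt_hi:
        return (cv.vern_t_max - tmean) / (cv.vern_t_max - cv.vern_t_opt_hi)
    return 1.0


def _photoperiod_factor(dl: float, cv: CultivarParams) -> float:
    """Development-rate multiplier for daylength below saturation."""
    if dl >= cv.daylength_saturation:
        return 1.0
    f = 1.0 - cv.photoperiod_sens * (cv.daylength_saturation - dl) / cv.daylength_saturation
    return min(1.0, max(0.0, f))


def grain_set_factor(
    mean_drought_stress: float,
    heat_degree_days: float,
    cultivar: CultivarParams,
) -> float:
    """Fertile-grain-number multiplier from stress around flowering.

    ``mean_drought_stress`` is the mean of (1 - choking factor) over the
    anthesis window; ``heat_degree_days`` the accumulated degree-days of
    Tmax above the damage threshold over the same window. A cultivar with
    both sensitivity flags off returns exactly 1. Each active response is
    linear in its exposure and floored, and the responses multiply.
    """
    factor = 1.0
    if cultivar.drought_sensitive:
        factor *= max(
            cultivar.grain_set_floor, 1.0 - cultivar.drought_slope * mean_drought_stress
        )
    if cultivar.heat_sensitive:
        factor *= max(
            cultivar.grain_set_floor, 1.0 - cultivar.heat_slope * heat_degree_days
        )
    return factor


def _infiltrate(sw: np.ndarray, cap: float, rain: float) -> float:
    """Fill layers top-down with rain; return drainage below the profile."""
    if rain <= 0.0:
        return 0.0
    deficit = cap - sw
    np.clip(deficit, 0.0, None, out=deficit)
    cum_before = np.cumsum(deficit) - deficit
    added = np.clip(rain - cum_before, 0.0, deficit)
    sw += added
    return max(0.0, rain - float(added.sum()))


def _extract(sw: np.ndarray, n_layers: int, demand: float) -> float:
    """Withdraw up to ``demand`` mm from the top ``n_layers`` layers.

    Extraction is proportional to each layer's current content, so no layer
    goes negative; returns the amount actually withdrawn.
    """
    if demand <= 0.0 or n_layers <= 0:
        return 0.0
    zone = sw[:n_layers]
    available = float(zone.sum())
    if available <= 0.0:
        return 0.0
    actual = min(demand, available)
    zone -= zone * (actual / available)
    return actual


def soil_water_update(
    sw: np.ndarray,
    layer_capacity: float,
    rain: float,
    evap_demand: float,
    transp_demand: float,
    n_evap_layers: int,
    n_root_layers: int,
) -> tuple[float, float, float]:
    """One day of the layered bucket water balance, in place.

    Rain infiltrates top-down, filling each 5-cm layer to capacity; excess
    past the bottom layer leaves as drainage. Soil evaporation is drawn from
    the top ``n_evap_layers`` and transpiration from the current root zone,
    each capped by the water actually present (extraction proportional to
    layer content, so stores never go negative).

    Returns ``(evap_actual, transp_actual, drainage)`` in mm; by
    construction rain - d(total water) - evap - transpiration - drainage
    closes to floating rounding.
    """
    if evap_demand < 0 or transp_demand < 0:
        raise ValueError("water demands must be non-negative")
    if rain < 0:
        raise ValueError("rain must be non-negative")
    drainage = _infiltrate(sw, layer_capacity, rain)
    evap = _extract(sw, n_evap_layers, evap_demand)
    transp = _extract(sw, n_root_layers, transp_demand)
    return evap, transp, drainage


@dataclass
class _SeasonArrays:
    """Weather-derived daily arrays precomputed once per season."""

    doy: np.ndarray
    tt: np.ndarray
    tmean: np.ndarray
    rain: np.ndarray
    srad: np.ndarray
    pet: np.ndarray
    photoperiod: np.ndarray
    f_temp: np.ndarray
    heat_dd: np.ndarray
    vern_eff: np.ndarray
    sow_index: int


def _precompute(
    weather: WeatherSeries,
    cultivar: CultivarParams,
    sowing_doy: int,
    latitude: float,
) -> _SeasonArrays:
    idx = np.flatnonzero(weather.doy == sowing_doy)
    if len(idx) == 0:
        raise ValueError(f"sowing day {sowing_doy} not present in weather series")
    sow = int(idx[0])
    tmean = weather.tmean
    tt = np.maximum(0.0, tmean - cultivar.t_base)
    s = 4098.0 * (0.6108 * np.exp(17.27 * tmean / (tmean + 237.3))) / (tmean + 237.3) ** 2
    pet = np.maximum(
        0.0,
        _PT_ALPHA * s / (s + _PSYCHROMETRIC) * _NET_RADIATION_FRAC * weather.srad / _LATENT_HEAT,
    )
    dl = daylength(latitude, weather.doy)
    pp = 1.0 - cultivar.photoperiod_sens * np.clip(
        (cultivar.daylength_saturation - dl) / cultivar.daylength_saturation, 0.0, None
    )
    pp = np.clip(pp, 0.0, 1.0)
    # Assimilation responds to daytime temperature, approximated as the mean
    # of the daily mean and the maximum.
    t_day = 0.5 * (tmean + weather.tmax)
    f_temp = np.clip((t_day - cultivar.t_base) / cultivar.temp_response_range, 0.0, 1.0)
    heat_dd = np.maximum(0.0, weather.tmax - cultivar.heat_threshold)
    # Trapezoidal vernalization effectiveness, vectorized.
    cv = cultivar
    vern = np.zeros_like(tmean)
    rising = (tmean > cv.vern_t_min) & (tmean < cv.vern_t_opt_lo)
    vern[rising] = (tmean[rising] - cv.vern_t_min) / (cv.vern_t_opt_lo - cv.vern_t_min)
    falling = (tmean > cv.vern_t_opt_hi) & (tmean < cv.vern_t_max)
    vern[falling] = (cv.vern_t_max - tmean[falling]) / (cv.vern_t_max - cv.vern_t_opt_hi)
    vern[(tmean >= cv.vern_t_opt_lo) & (tmean <= cv.vern_t_opt_hi)] = 1.0
    return _SeasonArrays(
        doy=weather.doy,
        tt=tt,
        tmean=tmean,
        rain=weather.rain,
        srad=weather.srad,
        pet=pet,
        photoperiod=pp,
        f_temp=f_temp,
        heat_dd=heat_dd,
        vern_eff=vern,
        sow_index=sow,
    )


def _simulate(
    arrays: _SeasonArrays,
    cultivar: CultivarParams,
    soil: SoilProfile,
    co2_ppm: float,
    water_limited: bool,
) -> SeasonResult:
    cv = cultivar
    co2f = co2_rue_factor(co2_ppm)
    cap = soil.layer_capacity
    sw = np.full(soil.n_layers, soil.initial_fill * cap)
    n_evap = soil.n_evap_layers
    theta = cv.choking_threshold

    n = len(arrays.doy)
    sow = arrays.sow_index

    # Phenology state
    stage = 0  # 0 sown, 1 emerged (vegetative), 2 grain fill, 3 mature
    tt_since_sowing = 0.0
    dev_tt = 0.0
    fill_tt = 0.0
    vern_progress = 0.0
    anthesis_i = None
    maturity_i = None

    # Canopy / carbon state
    lai = 0.0
    lai_at_anthesis = 0.0
    biomass = 0.0
    ear_mass = 0.0
    grain_mass = 0.0
    grain_number = 0.0
    grain_cap = math.inf
    remob_pool = 0.0
    remob_pool_initial = 0.0

    # Anthesis stress-window bookkeeping
    window = cv.stress_window
    recent_stress: list[float] = []   # rolling (1 - f_water) before anthesis
    recent_heat: list[float] = []
    window_stress_sum = 0.0
    window_heat_sum = 0.0
    window_days = 0
    window_closed = not (cv.drought_sensitive or cv.heat_sensitive)
    swd_anthesis = 0.0

    # Diagnostics
    season_et = 0.0
    rain_total = 0.0
    temp_sum = 0.0
    intercepted = 0.0
    wb_err = 0.0

    for i in range(sow, n):
        tt = arrays.tt[i]
        tmean = arrays.tmean[i]
        rain = arrays.rain[i]
        pet = arrays.pet[i]

        temp_sum += tt
        rain_total += rain
        tt_since_sowing += tt

        # --- Phenology -------------------------------------------------
        if stage == 0:
            if tt_since_sowing >= cv.emergence_tt:
                stage = 1
        elif stage == 1:
            vern_progress = min(1.0, vern_progress + arrays.vern_eff[i] / cv.vern_full)
            dev = tt * arrays.photoperiod[i]
            dev_tt += dev
            fln = cv.max_leaf_number - (cv.max_leaf_number - cv.min_leaf_number) * vern_progress
            # Canopy expansion tied to leaf stage
            lai = min(
                cv.lai_max,
                lai + cv.lai_max * dev / (cv.phyllochron * fln),
            )
            if dev_tt >= cv.phyllochron * (fln + 2.5):
                stage = 2
                anthesis_i = i
                ear_mass = cv.ear_partition * biomass
                remob_pool = cv.remobilization_frac * biomass
                remob_pool_initial = remob_pool
                lai_at_anthesis = lai
                swd_anthesis = soil.awc_total - float(sw.sum())
        # (grain-fill thermal time and senescence handled after water below)

        # --- Water balance --------------------------------------------
        root_depth = min(cv.root_growth_rate * tt_since_sowing, soil.depth_mm)
        root_layers = max(1, min(soil.n_layers, math.ceil(root_depth / 50.0)))
        rz = sw[:root_layers]
        rz_total = float(rz.sum())
        rz_cap = cap * root_layers
        ftsw = min(1.0, rz_total / rz_cap) if rz_cap > 0 else 0.0
        fw = water_stress_factor(ftsw, theta) if water_limited else 1.0

        fint = 1.0 - math.exp(-cv.k_ext * lai) if lai > 0 else 0.0

        ev_total = float(sw[:n_evap].sum())
        ftsw_e = min(1.0, ev_total / (cap * n_evap))
        f_evap = water_stress_factor(ftsw_e, theta)

        # Choking throttles assimilation and soil evaporation; transpiration
        # demand is limited only by canopy cover and layer supply, so dry
        # spells keep drawing the profile down.
        transp_demand = pet * fint
        evap_demand = pet * (1.0 - fint) * f_evap

        before = float(sw.sum())
        evap_actual, transp_actual, drainage = soil_water_update(
            sw, cap, rain, evap_demand, transp_demand, n_evap, root_layers
        )
        after = float(sw.sum())
        residual = rain - (after - before) - evap_actual - transp_actual - drainage
        wb_err = max(wb_err, abs(residual))
        season_et += evap_actual + transp_actual

        # --- Growth ----------------------------------------------------
        if stage >= 1 and stage < 3:
            par = 0.5 * arrays.srad[i]
            intercepted_today = par * fint
            intercepted += intercepted_today
            db = cv.rue * co2f * intercepted_today * arrays.f_temp[i] * fw
            biomass += db
        else:
            db = 0.0

        # --- Anthesis stress window ------------------------------------
        if not window_closed:
            stress_today = 1.0 - fw
            heat_today = arrays.heat_dd[i]
            if anthesis_i is None:
                recent_stress.append(stress_today)
                recent_heat.append(heat_today)
                if len(recent_stress) > window:
                    recent_stress.pop(0)
                    recent_heat.pop(0)
            else:
                if window_days == 0:
                    # Window opened: seed with the pre-anthesis days + today.
                    window_stress_sum = sum(recent_stress) + stress_today
                    window_heat_sum = sum(recent_heat) + heat_today
                    window_days = len(recent_stress) + 1
                elif i - anthesis_i <= window:
                    window_stress_sum += stress_today
                    window_heat_sum += heat_today
                    window_days += 1
                if i - anthesis_i >= window:
                    window_closed = True
                    mean_stress = window_stress_sum / max(1, window_days)
                    gsf = grain_set_factor(mean_stress, window_heat_sum, cv)
                    grain_number = ear_mass * cv.grains_per_ear_mass * gsf
                    grain_cap = grain_number * cv.potential_grain_weight * 1e-3  # mg->g m-2
                    grain_mass = min(grain_mass, grain_cap)

        if window_closed and grain_number == 0.0 and anthesis_i is not None and not (
            cv.drought_sensitive or cv.heat_sensitive
        ):
            grain_number = ear_mass * cv.grains_per_ear_mass
            grain_cap = grain_number * cv.potential_grain_weight * 1e-3
        # --- Grain fill and senescence ----------------------------------
        if stage == 2:
            fill_tt += tt
            # Stem-reserve remobilization paced by grain-fill progress
            remob_today = min(
                remob_pool, remob_pool_initial * tt / cv.grain_fill_duration
            )
            remob_pool -= remob_today
            grain_mass = min(grain_mass + db + remob_today, grain_cap)
            # Senescence accelerated by water stress
            sen = lai_at_anthesis * tt / cv.grain_fill_duration
            sen *= 1.0 + cv.senescence_stress_accel * (1.0 - fw)
            lai = max(0.0, lai - sen)
            if fill_tt >= cv.grain_fill_duration:
                stage = 3
                maturity_i = i
                break

    if anthesis_i is None:
        return SeasonResult(
            yield_t_ha=0.0, anthesis_doy=None, maturity_doy=None,
            season_et=season_et, swd_anthesis=float("nan"), temp_sum=temp_sum,
            rain_total=rain_total, intercepted_rad=intercepted, biomass=biomass,
            grain_number=0.0, failed=True,
            failure_reason="anthesis not reached before end of weather series",
            water_balance_error=wb_err,
        )
    if maturity_i is None:
        return SeasonResult(
            yield_t_ha=0.0, anthesis_doy=int(arrays.doy[anthesis_i]),
            maturity_doy=None, season_et=season_et, swd_anthesis=swd_anthesis,
            temp_sum=temp_sum, rain_total=rain_total, intercepted_rad=intercepted,
            biomass=biomass, grain_number=grain_number, failed=True,
            failure_reason="maturity not reached before end of weather series",
            water_balance_error=wb_err,
        )
    return SeasonResult(
        yield_t_ha=grain_mass / 100.0,
        anthesis_doy=int(arrays.doy[anthesis_i]),
        maturity_doy=int(arrays.doy[maturity_i]),
        season_et=season_et,
        swd_anthesis=swd_anthesis,
        temp_sum=temp_sum,
        rain_total=rain_total,
        intercepted_rad=intercepted,
        biomass=biomass,
        grain_number=grain_number,
        failed=False,
        water_balance_error=wb_err,
    )


def run_season(
    weather: WeatherSeries,
    cultivar: CultivarParams,
    soil: SoilProfile,
    co2_ppm: float,
    water_limited: bool = True,
    sowing_doy: int = SOWING_DOY_DEFAULT,
    latitude: float = 52.0,
) -> SeasonResult:
    """Simulate one season from sowing to maturity.

    The simulator is deterministic: identical inputs give identical results.
    A season whose weather ends before anthesis or maturity is returned with
    ``failed=True`` rather than raising, so callers can count and exclude
    failed seasons explicitly.
    """
    arrays = _precompute(weather, cultivar, sowing_doy, latitude)
    return _simulate(arrays, cultivar, soil, co2_ppm, water_limited)


def run_cultivar_set(
    weather: WeatherSeries,
    base_cultivar: CultivarParams,
    soil: SoilProfile,
    co2_ppm: float,
    sowing_doy: int = SOWING_DOY_DEFAULT,
    latitude: float = 52.0,
) -> CultivarSetResult:
    """Run the four-yield design on identical weather.

    Potential (no water limitation, stress-tolerant), water-limited
    tolerant, water-limited drought-sensitive and water-limited
    heat-sensitive variants of ``base_cultivar`` are simulated on the same
    weather series; only the sensitivity flags and the water-limitation
    switch differ between runs.
    """
    tolerant = replace(base_cultivar, drought_sensitive=False, heat_sensitive=False)
    arrays = _precompute(weather, tolerant, sowing_doy, latitude)
    rp = _simulate(arrays, tolerant, soil, co2_ppm, water_limited=False)
    rw = _simulate(arrays, tolerant, soil, co2_ppm, water_limited=True)
    rwd = _simulate(
        arrays,
        replace(base_cultivar, drought_sensitive=True, heat_sensitive=False),
        soil, co2_ppm, water_limited=True,
    )
    rwh = _simulate(
        arrays,
        replace(base_cultivar, drought_sensitive=False, heat_sensitive=True),
        soil, co2_ppm, water_limited=True,
    )
    failed = any(r.failed for r in (rp, rw, rwd, rwh))
    return CultivarSetResult(
        yp=rp.yield_t_ha, yw=rw.yield_t_ha, ywd=rwd.yield_t_ha, ywh=rwh.yield_t_ha,
        diagnostics=rw, failed=failed,
    )
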