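"""Configuration files, weather CSV I/O and the bundled demo fixture.

Site climatologies, climate scenarios, cultivars, soils and run manifests
are serialized as YAML mappings with strict key checking (unknown keys are
rejected, which catches typos early). Daily weather travels as plain CSV
with the fixed header ``site,year,doy,tmin,tmax,rain,srad`` on the package's
non-leap 365-day calendar; missing values are forbidden.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .crop import SOWING_DOY_DEFAULT, CultivarParams, SoilProfile
from .weather import (
    BASELINE_CO2_PPM,
    ClimateScenario,
    SiteClimate,
    WeatherSeries,
    make_gcm_ensemble,
)

__all__ = [
    "WEATHER_CSV_COLUMNS",
    "read_weather_csv",
    "write_weather_csv",
    "load_site_climate",
    "load_scenario",
    "load_cultivar",
    "load_soil",
    "RunManifest",
    "load_manifest",
    "save_manifest",
    "DemoFixture",
    "make_demo_fixture",
]

WEATHER_CSV_COLUMNS = ["site", "year", "doy", "tmin", "tmax", "rain", "srad"]


def write_weather_csv(series_list: Sequence[WeatherSeries], path) -> None:
    """Write weather series as CSV (365-day calendar, one row per day)."""
    frames = [s.to_frame() for s in series_list]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6f")


def read_weather_csv(path) -> list[WeatherSeries]:
    """Read weather series from CSV, validating structure and invariants.

    Rows must be grouped by (site, year) in day order; each group becomes
    one :class:`WeatherSeries`. Errors report the offending CSV line.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no weather rows")
    if list(df.columns) != WEATHER_CSV_COLUMNS:
        raise ValueError(
            f"{path}: header {list(df.columns)} != expected {WEATHER_CSV_COLUMNS}"
        )
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing value at data row {row + 1}")
    bad = df["tmin"] > df["tmax"]
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"{path}: tmin > tmax at data row {row + 1}")
    out = []
    for (site, year), g in df.groupby(["site", "year"], sort=False):
        try:
            out.append(
                WeatherSeries(
                    site_id=str(site),
                    harvest_year=int(year),
                    doy=g["doy"].to_numpy(),
                    tmin=g["tmin"].to_numpy(),
                    tmax=g["tmax"].to_numpy(),
                    rain=g["rain"].to_numpy(),
                    srad=g["srad"].to_numpy(),
                )
            )
        except ValueError as exc:
            first = int(g.index[0])
            raise ValueError(
                f"{path}: invalid series for site={site} year={year} "
                f"(starting data row {first + 1}): {exc}"
            ) from exc
    return out


def _strict_kwargs(mapping: Mapping, cls, context: str) -> dict:
    if not isinstance(mapping, Mapping):
        raise ValueError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    return dict(mapping)


def _load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ValueError(f"{path}: empty file")
    return data


def site_climate_from_dict(data: Mapping, context: str = "site") -> SiteClimate:
    return SiteClimate(**_strict_kwargs(data, SiteClimate, context))


def scenario_from_dict(data: Mapping, context: str = "scenario") -> ClimateScenario:
    return ClimateScenario(**_strict_kwargs(data, ClimateScenario, context))


def cultivar_from_dict(data: Mapping, context: str = "cultivar") -> CultivarParams:
    return CultivarParams(**_strict_kwargs(data, CultivarParams, context))


def soil_from_dict(data: Mapping, context: str = "soil") -> SoilProfile:
    return SoilProfile(**_strict_kwargs(data, SoilProfile, context))


def load_site_climate(path) -> SiteClimate:
    return site_climate_from_dict(_load_yaml(path), str(path))


def load_scenario(path) -> ClimateScenario:
    return scenario_from_dict(_load_yaml(path), str(path))


def load_cultivar(path) -> CultivarParams:
    return cultivar_from_dict(_load_yaml(path), str(path))


def load_soil(path) -> SoilProfile:
    return soil_from_dict(_load_yaml(path), str(path))


def _to_plain(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, np.ndarray):
            v = [float(x) for x in v]
        out[f.name] = v
    return out


@dataclass
class RunManifest:
    """A complete, self-contained ensemble-run specification."""

    sites: list[SiteClimate]
    scenario_groups: dict[str, list[ClimateScenario]]
    cultivar: CultivarParams = field(default_factory=CultivarParams)
    soil: SoilProfile = field(default_factory=SoilProfile)
    sowing_doy: int = SOWING_DOY_DEFAULT
    n_years: int = 100
    master_seed: int = 0

    def __post_init__(self):
        if not self.sites:
            raise ValueError("manifest needs at least one site")
        if not self.scenario_groups:
            raise ValueError("manifest needs at least one scenario group")
        if not 1 <= self.sowing_doy <= 365:
            raise ValueError("sowing_doy must lie in 1..365")
        if self.n_years < 2:
            raise ValueError("n_years must be at least 2")


_MANIFEST_KEYS = {
    "sites", "scenario_groups", "cultivar", "soil",
    "sowing_doy", "n_years", "master_seed",
}


def load_manifest(path) -> RunManifest:
    """Load and validate a YAML run manifest.

    Sites and scenarios are given inline as mappings. ``cultivar`` and
    ``soil`` are optional and default to the packaged winter wheat on the
    medium-AWC (177 mm) profile; the default sowing day is 20 October and
    an absent scenario group list is an error.
    """
    data = _load_yaml(path)
    unknown = set(data) - _MANIFEST_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown manifest keys {sorted(unknown)}")
    sites = [
        site_climate_from_dict(d, f"{path}: sites[{i}]")
        for i, d in enumerate(data.get("sites", []))
    ]
    groups = {
        str(label): [
            scenario_from_dict(d, f"{path}: scenario_groups[{label}][{i}]")
            for i, d in enumerate(members)
        ]
        for label, members in data.get("scenario_groups", {}).items()
    }
    cultivar = cultivar_from_dict(data["cultivar"], f"{path}: cultivar") \
        if "cultivar" in data else CultivarParams()
    soil = soil_from_dict(data["soil"], f"{path}: soil") if "soil" in data else SoilProfile()
    return RunManifest(
        sites=sites,
        scenario_groups=groups,
        cultivar=cultivar,
        soil=soil,
        sowing_doy=int(data.get("sowing_doy", SOWING_DOY_DEFAULT)),
        n_years=int(data.get("n_years", 100)),
        master_seed=int(data.get("master_seed", 0)),
    )


def save_manifest(manifest: RunManifest, path) -> None:
    """Write a manifest back to YAML (round-trips through load_manifest)."""
    data = {
        "sites": [_to_plain(s) for s in manifest.sites],
        "scenario_groups": {
            label: [_to_plain(s) for s in members]
            for label, members in manifest.scenario_groups.items()
        },
        "cultivar": _to_plain(manifest.cultivar),
        "soil": _to_plain(manifest.soil),
        "sowing_doy": manifest.sowing_doy,
        "n_years": manifest.n_years,
        "master_seed": manifest.master_seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Demo fixture: two contrasting GB-like sites at desk scale.
# ---------------------------------------------------------------------------

#: Monthly mean temperature (deg C), Jan..Dec, southeast-England-like.
_DRY_SE_TMEAN = [4.0, 4.2, 6.3, 8.7, 11.9, 14.9, 17.2, 17.0, 14.5, 11.0, 7.0, 4.5]
#: Northwest-England-like: cooler, much wetter.
_WET_NW_TMEAN = [3.5, 3.7, 5.4, 7.5, 10.4, 13.0, 15.0, 14.8, 12.8, 9.8, 6.3, 4.2]

_DRY_SE_TRANGE = [6.0, 6.5, 7.5, 8.5, 9.0, 9.0, 9.0, 8.5, 8.0, 7.0, 6.0, 5.5]
_WET_NW_TRANGE = [5.5, 6.0, 6.5, 7.5, 8.0, 7.5, 7.5, 7.5, 7.0, 6.0, 5.5, 5.0]

#: Mean wet-day rainfall (mm), mild winter maximum in the west.
_DRY_SE_WETMEAN = [4.5, 4.0, 4.0, 4.2, 4.5, 4.8, 5.2, 5.5, 5.0, 5.0, 5.0, 4.8]
_WET_NW_WETMEAN = [7.0, 6.0, 5.5, 5.0, 5.0, 5.5, 6.0, 6.5, 6.5, 7.0, 7.5, 7.5]


def demo_dry_site() -> SiteClimate:
    """A dry, warm southeast-GB-like site (annual rainfall ~ 600 mm)."""
    return SiteClimate(
        site_id="demo-dry-SE",
        latitude=51.8,
        monthly_tmean=_DRY_SE_TMEAN,
        monthly_trange=_DRY_SE_TRANGE,
        temp_sd=2.2,
        temp_ar1=0.7,
        p_wet_given_dry=0.25,
        p_wet_given_wet=0.55,
        gamma_shape=0.75,
        gamma_mean_wet=_DRY_SE_WETMEAN,
        srad_clearness=0.47,
    )


def demo_wet_site() -> SiteClimate:
    """A wet, cool northwest-GB-like site (annual rainfall ~ 1200 mm)."""
    return SiteClimate(
        site_id="demo-wet-NW",
        latitude=54.5,
        monthly_tmean=_WET_NW_TMEAN,
        monthly_trange=_WET_NW_TRANGE,
        temp_sd=2.0,
        temp_ar1=0.7,
        p_wet_given_dry=0.40,
        p_wet_given_wet=0.70,
        gamma_shape=0.75,
        gamma_mean_wet=_WET_NW_WETMEAN,
        srad_clearness=0.42,
    )


@dataclass
class DemoFixture:
    """A desk-scale end-to-end configuration (2 sites, 3 members per RCP)."""

    manifest: RunManifest


def make_demo_fixture(
    seed: int, n_years: int = 30, n_members: int = 3
) -> DemoFixture:
    """Build the bundled demo: dry-southeast vs wet-northwest GB-like sites.

    The precipitation contrast between the two sites exercises the
    north/south water-deficit gradient; the scenario groups are the
    baseline plus small synthetic GCM-like ensembles for each pathway.
    Fully determined by ``seed``.
    """
    root = np.random.SeedSequence(seed)
    s45, s85 = root.spawn(2)
    groups = {
        "baseline": [ClimateScenario.baseline()],
        "RCP4.5": make_gcm_ensemble(n_members, "RCP4.5", s45),
        "RCP8.5": make_gcm_ensemble(n_members, "RCP8.5", s85),
    }
    manifest = RunManifest(
        sites=[demo_dry_site(), demo_wet_site()],
        scenario_groups=groups,
        cultivar=CultivarParams(name="Mercia-like winter wheat"),
        soil=SoilProfile(awc_total=177.0),
        sowing_doy=SOWING_DOY_DEFAULT,
        n_years=n_years,
        master_seed=seed,
    )
    return DemoFixture(manifest=manifest)
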