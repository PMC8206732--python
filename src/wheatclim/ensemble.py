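"""Ensemble orchestration: sites x scenarios x years, and risk summaries.

A "cell" is one site under one climate scenario; running a cell generates
``n_years`` of synthetic weather, simulates the four-yield cultivar design
each year, and condenses the results into a :class:`SiteScenarioSummary`
(mean yield, interannual CV, index percentiles, phenology and water-balance
means). Across the members of a GCM-like scenario ensemble, any scalar
metric can be summarized as boxplot statistics (median, quartiles, 10/90
whiskers, outliers beyond the whiskers). Percentile levels map to mean
recurrence intervals via 1/(1-q): the 50/75/90/95th percentiles correspond
to losses recurring every 2, 4, 10 and 20 years.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crop import (
    SOWING_DOY_DEFAULT,
    CultivarParams,
    CultivarSetResult,
    SoilProfile,
    run_cultivar_set,
)
from .indices import (
    PERCENTILE_LEVELS,
    IndexPercentiles,
    StressIndices,
    coefficient_of_variation,
    compute_indices,
    index_percentiles,
)
from .weather import ClimateScenario, SiteClimate, apply_scenario, generate_weather

__all__ = [
    "SiteScenarioSummary",
    "BoxplotStats",
    "cell_seed",
    "run_site_scenario",
    "boxplot_stats",
    "spatial_average",
    "recurrence_interval",
    "loss_frequency_curve",
    "run_ensemble",
    "EnsembleResult",
]

_MEAN_FIELDS = (
    "mean_yield",
    "cv",
    "mean_anthesis_doy",
    "mean_maturity_doy",
    "mean_season_et",
    "mean_swd_anthesis",
    "mean_temp_sum",
    "mean_rain_total",
    "mean_intercepted_rad",
)


@dataclass
class SiteScenarioSummary:
    """Risk summary of one site under one scenario over ``n_years`` seasons.

    ``mean_yield`` and ``cv`` refer to the water-limited yield of the
    flowering-tolerant cultivar (Yw), whose run also supplies the phenology
    and water-balance diagnostics. Means are over successful seasons only.
    """

    site_id: str
    scenario: str
    n_years: int
    n_failed: int
    mean_yield: float
    cv: float
    wsi_percentiles: IndexPercentiles
    dsi_percentiles: IndexPercentiles
    hsi_percentiles: IndexPercentiles
    mean_anthesis_doy: float
    mean_maturity_doy: float
    mean_season_et: float
    mean_swd_anthesis: float
    mean_temp_sum: float
    mean_rain_total: float
    mean_intercepted_rad: float
    high_failure: bool = False


@dataclass(frozen=True)
class BoxplotStats:
    """Median, quartile box, 10/90 whiskers and outliers beyond them."""

    median: float
    q25: float
    q75: float
    p10: float
    p90: float
    outliers: tuple[float, ...]

    def __post_init__(self):
        if not (self.p10 <= self.q25 <= self.median <= self.q75 <= self.p90):
            raise ValueError("boxplot statistics must be ordered")


def cell_seed(master_seed: int, site_id: str, scenario_label: str) -> int:
    """Deterministic per-(site, scenario) seed derived from a master seed.

    Stable across processes and run order, so ensemble cells can be computed
    in any order (or in parallel) with identical results.
    """
    tag = zlib.crc32(f"{site_id}|{scenario_label}".encode())
    return int(np.random.SeedSequence([master_seed, tag]).generate_state(1)[0] % (2**31))


def run_site_scenario(
    site_climate: SiteClimate,
    scenario: ClimateScenario,
    n_years: int,
    seed: int,
    cultivar: CultivarParams,
    soil: SoilProfile,
    sowing_doy: int = SOWING_DOY_DEFAULT,
) -> SiteScenarioSummary:
    """Simulate one ensemble cell and summarize it.

    Weather is generated from the scenario-perturbed climatology; the
    scenario's CO2 concentration drives the RUE fertilization factor. Failed
    seasons (weather ending before maturity) are excluded from all summary
    statistics and counted; the summary is flagged when more than 10% of
    seasons fail.
    """
    if n_years < 2:
        raise ValueError("n_years must be at least 2")
    perturbed = apply_scenario(site_climate, scenario)
    series_list = generate_weather(perturbed, n_years, seed)
    results: list[CultivarSetResult] = []
    for series in series_list:
        results.append(
            run_cultivar_set(
                series, cultivar, soil, scenario.co2_ppm,
                sowing_doy=sowing_doy, latitude=site_climate.latitude,
            )
        )
    return summarize_cell(site_climate.site_id, scenario.label, results)


def summarize_cell(
    site_id: str, scenario_label: str, results: Sequence[CultivarSetResult]
) -> SiteScenarioSummary:
    """Condense per-year four-yield results into a cell summary."""
    ok = [r for r in results if not r.failed]
    n_failed = len(results) - len(ok)
    if len(ok) < 2:
        raise ValueError(
            f"cell {site_id}/{scenario_label}: only {len(ok)} successful seasons"
        )
    yearly = [
        compute_indices(r.yp, r.yw, r.ywd, r.ywh, year=i) for i, r in enumerate(ok)
    ]
    yields = [r.yw for r in ok]
    diag = [r.diagnostics for r in ok]
    return SiteScenarioSummary(
        site_id=site_id,
        scenario=scenario_label,
        n_years=len(results),
        n_failed=n_failed,
        mean_yield=float(np.mean(yields)),
        cv=coefficient_of_variation(yields),
        wsi_percentiles=index_percentiles(yearly, "WSI"),
        dsi_percentiles=index_percentiles(yearly, "DSI"),
        hsi_percentiles=index_percentiles(yearly, "HSI"),
        mean_anthesis_doy=float(np.mean([d.anthesis_doy for d in diag])),
        mean_maturity_doy=float(np.mean([d.maturity_doy for d in diag])),
        mean_season_et=float(np.mean([d.season_et for d in diag])),
        mean_swd_anthesis=float(np.mean([d.swd_anthesis for d in diag])),
        mean_temp_sum=float(np.mean([d.temp_sum for d in diag])),
        mean_rain_total=float(np.mean([d.rain_total for d in diag])),
        mean_intercepted_rad=float(np.mean([d.intercepted_rad for d in diag])),
        high_failure=n_failed > 0.1 * len(results),
    )


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Five-number boxplot summary across ensemble members.

    Whiskers are the 10th and 90th percentiles; values outside them are
    listed as outliers (not the 1.5 x IQR convention).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    p10, q25, med, q75, p90 = np.quantile(arr, [0.10, 0.25, 0.50, 0.75, 0.90])
    out = tuple(float(v) for v in arr[(arr < p10) | (arr > p90)])
    return BoxplotStats(float(med), float(q25), float(q75), float(p10), float(p90), out)


def _avg_percentiles(groups: Sequence[IndexPercentiles]) -> IndexPercentiles:
    name = groups[0].index_name
    arrs = np.array([g.as_tuple() for g in groups])
    return IndexPercentiles(name, *arrs.mean(axis=0))


def spatial_average(summaries: Sequence[SiteScenarioSummary]) -> SiteScenarioSummary:
    """Unweighted metric-wise mean of per-site summaries for one scenario.

    Index percentiles are averaged percentile-wise (the spatial average of
    the sites' p95 values, etc.). Mixing scenarios is rejected.
    """
    if not summaries:
        raise ValueError("no summaries supplied")
    labels = {s.scenario for s in summaries}
    if len(labels) != 1:
        raise ValueError(f"summaries mix scenarios: {sorted(labels)}")
    first = summaries[0]
    kwargs = {
        name: float(np.mean([getattr(s, name) for s in summaries]))
        for name in _MEAN_FIELDS
    }
    return SiteScenarioSummary(
        site_id=f"spatial_mean({len(summaries)} sites)",
        scenario=first.scenario,
        n_years=first.n_years,
        n_failed=sum(s.n_failed for s in summaries),
        wsi_percentiles=_avg_percentiles([s.wsi_percentiles for s in summaries]),
        dsi_percentiles=_avg_percentiles([s.dsi_percentiles for s in summaries]),
        hsi_percentiles=_avg_percentiles([s.hsi_percentiles for s in summaries]),
        high_failure=any(s.high_failure for s in summaries),
        **kwargs,
    )


def recurrence_interval(q: float) -> float:
    """Mean recurrence interval (years) of exceeding the q-quantile loss."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    return 1.0 / (1.0 - q)


def loss_frequency_curve(summary: SiteScenarioSummary) -> pd.DataFrame:
    """Water-stress loss level versus mean recurrence interval.

    Maps the 50/75/90/95th WSI percentiles to their 2/4/10/20-year
    recurrence intervals.
    """
    wsi = summary.wsi_percentiles.as_tuple()
    return pd.DataFrame(
        {
            "percentile": [int(100 * q) for q in PERCENTILE_LEVELS],
            "recurrence_years": [recurrence_interval(q) for q in PERCENTILE_LEVELS],
            "wsi": list(wsi),
        }
    )


@dataclass
class EnsembleResult:
    """Tabular outputs of a full sites x scenario-groups x years run."""

    yields: pd.DataFrame      # site, group, scenario, year, yp, yw, ywd, ywh
    summaries: pd.DataFrame   # one row per cell
    boxplots: pd.DataFrame    # per group x metric, across member scenarios
    loss_curves: pd.DataFrame
    cell_summaries: dict[tuple[str, str], SiteScenarioSummary]


_BOX_METRICS = ("mean_yield", "cv", "mean_anthesis_doy", "mean_maturity_doy")


def _summary_row(s: SiteScenarioSummary, group: str) -> dict:
    row = {
        "site": s.site_id,
        "group": group,
        "scenario": s.scenario,
        "n_years": s.n_years,
        "n_failed": s.n_failed,
    }
    for name in _MEAN_FIELDS:
        row[name] = getattr(s, name)
    for idx in ("wsi", "dsi", "hsi"):
        p = getattr(s, f"{idx}_percentiles")
        for lev, v in zip((50, 75, 90, 95), p.as_tuple()):
            row[f"{idx}{lev}"] = v
    return row


def run_ensemble(
    sites: Sequence[SiteClimate],
    scenario_groups: Mapping[str, Sequence[ClimateScenario]],
    n_years: int,
    master_seed: int,
    cultivar: CultivarParams,
    soil: SoilProfile,
    sowing_doy: int = SOWING_DOY_DEFAULT,
) -> EnsembleResult:
    """Run every site under every scenario of every group.

    ``scenario_groups`` maps a group label (e.g. "baseline", "RCP4.5") to
    its member scenarios; boxplot statistics are computed across members
    within a group, mirroring an ensemble of GCM projections. Per-cell seeds
    derive from ``master_seed`` so the run is order-independent and bitwise
    reproducible.
    """
    yield_rows = []
    summary_rows = []
    cells: dict[tuple[str, str], SiteScenarioSummary] = {}
    per_group_site: dict[str, dict[str, list[SiteScenarioSummary]]] = {}
    for group, scenarios in scenario_groups.items():
        per_group_site[group] = {}
        for site in sites:
            per_site = []
            for scen in scenarios:
                seed = cell_seed(master_seed, site.site_id, scen.label)
                perturbed = apply_scenario(site, scen)
                series_list = generate_weather(perturbed, n_years, seed)
                results = [
                    run_cultivar_set(
                        s, cultivar, soil, scen.co2_ppm,
                        sowing_doy=sowing_doy, latitude=site.latitude,
                    )
                    for s in series_list
                ]
                for yr, r in enumerate(results):
                    yield_rows.append(
                        {
                            "site": site.site_id,
                            "group": group,
                            "scenario": scen.label,
                            "year": yr,
                            "yp": r.yp,
                            "yw": r.yw,
                            "ywd": r.ywd,
                            "ywh": r.ywh,
                            "failed": r.failed,
                        }
                    )
                summ = summarize_cell(site.site_id, scen.label, results)
                cells[(site.site_id, scen.label)] = summ
                per_site.append(summ)
                summary_rows.append(_summary_row(summ, group))
            per_group_site[group][site.site_id] = per_site

    box_rows = []
    curve_rows = []
    for group, by_site in per_group_site.items():
        for site_id, summaries in by_site.items():
            for metric in _BOX_METRICS + ("wsi95", "dsi95", "hsi95"):
                if metric.endswith("95"):
                    vals = [
                        getattr(s, f"{metric[:-2]}_percentiles").p95 for s in summaries
                    ]
                else:
                    vals = [getattr(s, metric) for s in summaries]
                if len(vals) >= 2:
                    bs = boxplot_stats(vals)
                    box_rows.append(
                        {
                            "site": site_id,
                            "group": group,
                            "metric": metric,
                            "median": bs.median,
                            "q25": bs.q25,
                            "q75": bs.q75,
                            "p10": bs.p10,
                            "p90": bs.p90,
                            "n_outliers": len(bs.outliers),
                        }
                    )
        # Loss-frequency curve of the spatial average per group, built from
        # the member-median of each WSI percentile (then averaged over sites).
        for site_id, summaries in by_site.items():
            med = IndexPercentiles(
                "WSI",
                *(
                    float(np.median([s.wsi_percentiles.as_tuple()[k] for s in summaries]))
                    for k in range(4)
                ),
            )
            for q, lev in zip(PERCENTILE_LEVELS, (50, 75, 90, 95)):
                curve_rows.append(
                    {
                        "site": site_id,
                        "group": group,
                        "percentile": lev,
                        "recurrence_years": recurrence_interval(q),
                        "wsi": med.as_tuple()[(50, 75, 90, 95).index(lev)],
                    }
                )

    return EnsembleResult(
        yields=pd.DataFrame(yield_rows),
        summaries=pd.DataFrame(summary_rows),
        boxplots=pd.DataFrame(box_rows),
        loss_curves=pd.DataFrame(curve_rows),
        cell_summaries=cells,
    )
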