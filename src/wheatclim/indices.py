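"""Yield stress indices and their distributional summaries.

Three indices express proportional yield loss per simulated season:

* WSI = 1 - Yw/Yp — seasonal water stress (source-capacity loss);
* DSI = 1 - Ywd/Yw — drought around flowering (sink-capacity loss);
* HSI = 1 - Ywh/Yw — heat around flowering (sink-capacity loss);

where Yp is potential yield, Yw water-limited yield of a flowering-tolerant
cultivar, and Ywd/Ywh water-limited yields of drought-/heat-sensitive
cultivars. Upper percentiles of the yearly index distribution quantify the
loss level exceeded with a given probability: the 95th percentile is the
loss reached or exceeded once in 20 years on average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "StressIndices",
    "IndexPercentiles",
    "compute_indices",
    "percentile",
    "coefficient_of_variation",
    "index_percentiles",
    "PERCENTILE_LEVELS",
]

#: The reported percentile levels of each index distribution.
PERCENTILE_LEVELS = (0.50, 0.75, 0.90, 0.95)

_REL_TOL = 1e-9


@dataclass(frozen=True)
class StressIndices:
    """Water, drought and heat stress indices for one simulated year."""

    year: int
    wsi: float
    dsi: float
    hsi: float


@dataclass(frozen=True)
class IndexPercentiles:
    """50/75/90/95th percentiles of one index's yearly distribution."""

    index_name: str
    p50: float
    p75: float
    p90: float
    p95: float

    def __post_init__(self):
        if not (self.p50 <= self.p75 <= self.p90 <= self.p95):
            raise ValueError("percentiles must be non-decreasing")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p50, self.p75, self.p90, self.p95)


def compute_indices(
    yp: float, yw: float, ywd: float, ywh: float, year: int = 0
) -> StressIndices:
    """Stress indices from the four-yield design of one season.

    Raises if the reference yields are non-positive or if a sensitive
    cultivar out-yields the tolerant one beyond floating tolerance — the
    latter signals a simulator defect, not a valid input.
    """
    if yp <= 0 or yw <= 0:
        raise ValueError("yp and yw must be positive to define the indices")
    tol = _REL_TOL * yw
    if ywd > yw + tol or ywh > yw + tol:
        raise ValueError(
            "sensitive-cultivar yield exceeds tolerant yield: "
            f"yw={yw}, ywd={ywd}, ywh={ywh}"
        )
    if yw > yp + _REL_TOL * yp:
        raise ValueError(f"water-limited yield exceeds potential: yp={yp}, yw={yw}")

    def _clamp(x: float) -> float:
        return min(1.0, max(0.0, x))

    return StressIndices(
        year=year,
        wsi=_clamp(1.0 - yw / yp),
        dsi=_clamp(1.0 - ywd / yw),
        hsi=_clamp(1.0 - ywh / yw),
    )


def percentile(sample: Sequence[float], q: float) -> float:
    """Empirical quantile with linear interpolation of order statistics.

    Uses the rule that places quantile ``q`` at position ``1 + q(n-1)`` of
    the sorted sample (the numpy/R-7 default).
    """
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError("sample must be non-empty")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    return float(np.quantile(arr, q, method="linear"))


def coefficient_of_variation(yields: Sequence[float]) -> float:
    """Sample coefficient of variation in percent (n-1 denominator sd)."""
    arr = np.asarray(yields, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(100.0 * arr.std(ddof=1) / mean)


def index_percentiles(
    yearly: Sequence[StressIndices], which: str
) -> IndexPercentiles:
    """50/75/90/95th percentiles of one index over a run of years."""
    name = which.lower()
    if name not in ("wsi", "dsi", "hsi"):
        raise ValueError(f"unknown index {which!r}; expected WSI, DSI or HSI")
    values = [getattr(s, name) for s in yearly]
    if not values:
        raise ValueError("no yearly indices supplied")
    if len(values) < 20:
        warnings.warn(
            f"only {len(values)} years supplied; upper percentiles will be noisy",
            stacklevel=2,
        )
    p = [percentile(values, q) for q in PERCENTILE_LEVELS]
    return IndexPercentiles(which.upper(), *p)
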