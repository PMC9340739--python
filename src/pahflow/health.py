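"""Lifetime lung-cancer burden from BaP exposure.

The dose-response model assumes constant exposure to the annual-mean
concentration c (ug m^-3) for a 70-year lifetime.  With URR the unit
relative risk at a cumulative exposure of 100 ug m^-3 years,

    rr(c)  = URR ** (c * 70 / 100)
    PAF    = (rr - 1) / rr

and the lifetime deaths in a grid cell are PAF times the cell's share of
the region's cumulative lung-cancer deaths over the 70-year horizon,
LD_m = sum_y LR_my / 1e5 * P_my (rates per 100,000 people per year).

URR values at the calibration exposure differ between macro-areas
(Asia 1.3, Europe 1.13, North America 1.16) with a world average of 1.2
applied everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ConcentrationField, RegionGrid

__all__ = [
    "LIFETIME_YEARS",
    "CALIBRATION_EXPOSURE",
    "DEFAULT_URR",
    "URRTable",
    "MortalitySeries",
    "BurdenField",
    "relative_risk",
    "paf",
    "lifetime_deaths",
    "attribute_scenario_deaths",
    "burden_from_concentration",
]

LIFETIME_YEARS = 70
CALIBRATION_EXPOSURE = 100.0  # ug m^-3 years

#: Unit relative risks at 100 ug m^-3 years cumulative BaP exposure.
DEFAULT_URR = {"asia": 1.3, "europe": 1.13, "north_america": 1.16}
WORLD_URR = 1.2


@dataclass
class URRTable:
    """Macro-area URR values and an optional per-cell area assignment.

    ``area_map`` holds an area label per grid cell; cells with labels not in
    ``values`` (or a ``None`` map) take the world default.
    """

    values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_URR))
    world_default: float = WORLD_URR
    area_map: np.ndarray | None = None

    def __post_init__(self):
        bad = {k: v for k, v in self.values.items() if v < 1.0}
        if bad or self.world_default < 1.0:
            raise ValueError(f"URR must be >= 1 (got {bad or self.world_default})")

    def per_cell(self, shape: tuple[int, int]) -> np.ndarray:
        urr = np.full(shape, self.world_default)
        if self.area_map is not None:
            if self.area_map.shape != shape:
                raise ValueError("area map shape does not match the grid")
            for area, value in self.values.items():
                urr[self.area_map == area] = value
        return urr


@dataclass
class MortalitySeries:
    """Regional lung-cancer rates and population over the lifetime horizon.

    ``LR[m, y]`` in deaths per 100,000 people per year; ``P[m, y]`` persons.
    """

    LR: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.LR = np.asarray(self.LR, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.LR.shape != self.P.shape or self.LR.shape[1] != LIFETIME_YEARS:
            raise ValueError(f"series must cover {LIFETIME_YEARS} years per region")
        if np.any(self.LR < 0) or np.any(self.P < 0):
            raise ValueError("rates and population must be nonnegative")

    def lifetime_lung_cancer_deaths(self) -> np.ndarray:
        """sum_y LR_my / 1e5 * P_my per region (all-cause-of-exposure pool)."""
        return (self.LR / 1e5 * self.P).sum(axis=1)


@dataclass
class BurdenField:
    """Gridded relative risk, PAF and lifetime deaths for one scenario."""

    rr: np.ndarray
    paf: np.ndarray
    deaths: np.ndarray
    regional: np.ndarray
    scenario: str = "base"
    year: int | None = None


def relative_risk(
    c: ConcentrationField | np.ndarray,
    urr: URRTable,
    dose_response: str = "exponential",
) -> np.ndarray:
    """Lifetime relative risk per cell.

    ``dose_response='linear'`` replaces the exponential model by its
    first-order expansion rr = 1 + ln(URR) * c*70/100, making the whole
    burden calculation linear in concentration (used to verify the
    decomposition's linear limit, not for reported burdens).
    """
    values = c.values if isinstance(c, ConcentrationField) else np.asarray(c, float)
    if np.any(values < 0):
        raise ValueError("concentrations must be nonnegative")
    u = urr.per_cell(values.shape)
    cumulative = values * (LIFETIME_YEARS / CALIBRATION_EXPOSURE)
    if dose_response == "exponential":
        return u ** cumulative
    if dose_response == "linear":
        return 1.0 + np.log(u) * cumulative
    raise ValueError(f"unknown dose_response {dose_response!r}")


def paf(rr: np.ndarray) -> np.ndarray:
    """Population attributable fraction (rr - 1) / rr."""
    rr = np.asarray(rr, dtype=float)
    if np.any(rr < 1.0):
        raise ValueError("relative risk below 1")
    return (rr - 1.0) / rr


def lifetime_deaths(
    paf_grid: np.ndarray,
    ms: MortalitySeries,
    grid: RegionGrid,
    scenario: str = "base",
    year: int | None = None,
    rr: np.ndarray | None = None,
) -> BurdenField:
    """Lifetime attributable deaths per cell and per region.

    Regional populations are spread over cells by the population weight
    grid; the lung-cancer rate is region-constant, so the cell's lifetime
    death pool is its population share of the regional pool.
    """
    if ms.LR.shape[0] != grid.n_regions:
        raise ValueError("mortality series and grid disagree on region count")
    ld_region = ms.lifetime_lung_cancer_deaths()
    pool = np.tensordot(ld_region, grid.population_weights, axes=(0, 0))
    deaths = paf_grid * pool
    regional = grid.region_sums(deaths)
    if rr is None:
        rr = 1.0 / (1.0 - np.clip(paf_grid, 0.0, 1.0 - 1e-300))
    return BurdenField(rr=rr, paf=paf_grid, deaths=deaths, regional=regional,
                       scenario=scenario, year=year)


def attribute_scenario_deaths(
    base: BurdenField, fraction: np.ndarray, grid: RegionGrid, scenario: str = "scenario"
) -> BurdenField:
    """Scenario deaths = base deaths x per-cell concentration fraction."""
    fraction = np.asarray(fraction, dtype=float)
    if fraction.shape != base.deaths.shape:
        raise ValueError("fraction grid shape mismatch")
    if np.any(fraction > 1.0 + 1e-9) or np.any(fraction < -1e-12):
        import warnings

        warnings.warn(
            "scenario fraction outside [0, 1]; upstream transport is expected to be linear",
            RuntimeWarning,
            stacklevel=2,
        )
    deaths = base.deaths * fraction
    return BurdenField(
        rr=base.rr, paf=base.paf * fraction, deaths=deaths,
        regional=grid.region_sums(deaths), scenario=scenario, year=base.year,
    )


def burden_from_concentration(
    c: ConcentrationField,
    urr: URRTable,
    ms: MortalitySeries,
    grid: RegionGrid,
    dose_response: str = "exponential",
) -> BurdenField:
    """Convenience chain: concentration -> rr -> PAF -> lifetime deaths.

    In linear mode the attributable fraction is taken as rr - 1 (the
    small-exposure limit of (rr-1)/rr), keeping deaths exactly linear in
    concentration.
    """
    if dose_response == "linear":
        # form the linear PAF directly from concentration: going through
        # 1 + x - 1 would lose precision at ambient-level exposures
        values = c.values
        if np.any(values < 0):
            raise ValueError("concentrations must be nonnegative")
        u = urr.per_cell(values.shape)
        paf_grid = np.log(u) * values * (LIFETIME_YEARS / CALIBRATION_EXPOSURE)
        rr = 1.0 + paf_grid
    else:
        rr = relative_risk(c, urr, dose_response=dose_response)
        paf_grid = paf(rr)
    return lifetime_deaths(paf_grid, ms, grid, scenario=c.scenario, year=c.year, rr=rr)
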