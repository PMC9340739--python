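"""Linear source-receptor transport surrogate.

A full chemical-transport simulation (gas-particle partitioning, oxidation,
deposition, re-emission) is deliberately not modelled here.  Every step of
the downstream analysis treats atmospheric transport as a black-box linear
map from an annual emission grid to an annual-mean surface concentration
grid, evaluated once per emission scenario, plus per-cell ratio attribution.
The surrogate preserves exactly those properties: it is a nonnegative linear
operator whose parameters (plume spread, zonal advection shift, dilution
amplitude) differ between meteorological years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ConcentrationField, GriddedEmissions

__all__ = ["TransferKernel", "simulate_concentration", "scenario_fraction"]


@dataclass(frozen=True)
class TransferKernel:
    """Separable Gaussian-blur-plus-advection operator on the emission grid.

    ``concentration = amplitude * blur(shift(emissions))`` with periodic
    wrapping in longitude and reflecting edges in latitude.  ``amplitude``
    converts emitted mass per cell-year into an annual-mean concentration
    (ug m^-3 per mass unit) and bundles dilution/loss; it varies between
    years as a stand-in for meteorological change.
    """

    sigma_lat: float = 1.2
    sigma_lon: float = 1.8
    shift_lon: int = 1
    amplitude: float = 5e-3
    year: int | None = None

    def __post_init__(self):
        if self.sigma_lat < 0 or self.sigma_lon < 0 or self.amplitude < 0:
            raise ValueError("kernel parameters must be nonnegative")

    def apply(self, emissions: np.ndarray) -> np.ndarray:
        e = np.asarray(emissions, dtype=float)
        shifted = np.roll(e, self.shift_lon, axis=1)
        blurred = ndimage.gaussian_filter(
            shifted, sigma=(self.sigma_lat, self.sigma_lon), mode=("reflect", "wrap")
        )
        return self.amplitude * blurred

    def __call__(self, emissions: np.ndarray) -> np.ndarray:
        return self.apply(emissions)


def simulate_concentration(em: GriddedEmissions, k: TransferKernel) -> ConcentrationField:
    """Annual-mean surface concentration field for one emission scenario."""
    values = k.apply(em.values)
    return ConcentrationField(values=values, scenario=em.scenario, year=k.year, species=em.species)


def scenario_fraction(scenario: ConcentrationField, base: ConcentrationField) -> np.ndarray:
    """Per-cell fractional contribution of a scenario to the base concentration.

    Cells where the base concentration is zero contribute no burden and get
    fraction 0.  When a set of scenarios' emissions partitions the base
    emissions, kernel linearity makes the fractions sum to 1 wherever the
    base is positive.
    """
    if scenario.values.shape != base.values.shape:
        raise ValueError("scenario and base concentration grids differ in shape")
    if scenario.year != base.year:
        raise ValueError("scenario and base concentrations must share the kernel year")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(base.values > 0, scenario.values / base.values, 0.0)
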