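"""Gridded spatial containers shared by the inventory, transport and health stages.

The study's spatial convention is a regular lat/lon cell-centre grid.  Each
region owns a contiguous block of cells; regional scalar quantities (emission
totals, population) are spread over the region's cells by fixed nonnegative
weight fields that sum to one within the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RegionGrid", "GriddedEmissions", "ConcentrationField", "strip_region_mask"]


def strip_region_mask(grid_shape: tuple[int, int], n_regions: int) -> np.ndarray:
    """Partition the grid into ``n_regions`` contiguous longitude strips."""
    n_lat, n_lon = grid_shape
    mask = np.zeros((n_lat, n_lon), dtype=np.int64)
    for m, cols in enumerate(np.array_split(np.arange(n_lon), n_regions)):
        mask[:, cols] = m
    return mask


@dataclass
class RegionGrid:
    """Region mask plus per-region spatial weight fields.

    ``mask[i, j]`` is the region index owning cell (i, j).
    ``emission_weights[m]`` and ``population_weights[m]`` are nonnegative
    fields supported on region m's cells, each summing to 1 over the region.
    """

    mask: np.ndarray
    emission_weights: np.ndarray  # (R, n_lat, n_lon)
    population_weights: np.ndarray  # (R, n_lat, n_lon)
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None

    @property
    def n_regions(self) -> int:
        return self.emission_weights.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def validate(self, atol: float = 1e-9) -> None:
        R = self.n_regions
        for name, w in (("emission", self.emission_weights), ("population", self.population_weights)):
            if w.shape != (R, *self.mask.shape):
                raise ValueError(f"{name} weights shape mismatch")
            if np.any(w < 0):
                raise ValueError(f"negative {name} weights")
            sums = w.reshape(R, -1).sum(axis=1)
            if np.abs(sums - 1.0).max() > atol:
                raise ValueError(f"{name} weights do not sum to 1 per region")
            off = w * (self.mask[None, :, :] != np.arange(R)[:, None, None])
            if np.abs(off).max() > atol:
                raise ValueError(f"{name} weights leak outside region masks")

    def region_sums(self, values: np.ndarray) -> np.ndarray:
        """Sum a grid field over each region's cells."""
        return np.array(
            [values[self.mask == m].sum() for m in range(self.n_regions)]
        )


@dataclass
class GriddedEmissions:
    """Mass emitted per grid cell and year (same mass unit as the inventory)."""

    values: np.ndarray
    species: str = "BaP"
    scenario: str = "base"
    year: int | None = None

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class ConcentrationField:
    """Annual-mean near-surface concentration per grid cell (ug m^-3)."""

    values: np.ndarray
    scenario: str = "base"
    year: int | None = None
    species: str = "BaP"
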