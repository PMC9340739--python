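"""Production-based PAH emission inventories.

Emissions of sector i in region m are the sum of fuel-combustion and
industrial-process terms,

    E_im = sum_k FC_im^k * EF_im^k + sum_p AR_im^p * EF_im^p,

where FC is fuel consumed by energy type k, AR the activity rate (product
output) of process p, and EF the matching emission factors.  Emission-factor
uncertainty is propagated by Monte-Carlo sampling of multiplicative
lognormal perturbations (median at the point factor), and regional totals
are distributed onto the grid by fixed spatial weights.

The inventory carries the 16 priority PAH congeners as species labels, but
the transport and health stages propagate only benzo[a]pyrene (BaP), the
congener whose toxicity dominates the health signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import GriddedEmissions, RegionGrid

__all__ = [
    "PRIORITY_PAHS",
    "FuelActivityTable",
    "EmissionFactorTable",
    "EmissionInventory",
    "compute_emissions",
    "monte_carlo_ci",
    "grid_emissions",
    "split_anthropogenic",
]

PRIORITY_PAHS = (
    "NAP", "ACE", "ACY", "FLU", "ANT", "PHE", "FLUH", "PYR",
    "BaA", "CHR", "BbF", "BkF", "BaP", "DBA", "IDP", "BgP",
)


@dataclass
class FuelActivityTable:
    """Fuel consumption FC (R, S, K) and process activity rates AR (R, S, P)."""

    FC: np.ndarray
    AR: np.ndarray
    fuel_labels: tuple[str, ...] = ()
    process_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.FC = np.asarray(self.FC, dtype=float)
        self.AR = np.asarray(self.AR, dtype=float)
        if np.any(self.FC < 0) or np.any(self.AR < 0):
            raise ValueError("fuel consumption and activity rates must be nonnegative")
        if not self.fuel_labels:
            self.fuel_labels = tuple(f"fuel{k}" for k in range(self.FC.shape[2]))
        if not self.process_labels:
            self.process_labels = tuple(f"proc{p}" for p in range(self.AR.shape[2]))


@dataclass
class EmissionFactorTable:
    """Source-specific emission factors with lognormal uncertainty scales.

    ``sigma_fuel`` / ``sigma_proc`` are the scales (std of log) of the
    multiplicative lognormal uncertainty on the matching factor; the point
    factor is the median of the distribution.
    """

    EF_fuel: np.ndarray
    EF_proc: np.ndarray
    sigma_fuel: np.ndarray | None = None
    sigma_proc: np.ndarray | None = None
    species: str = "BaP"

    def __post_init__(self):
        self.EF_fuel = np.asarray(self.EF_fuel, dtype=float)
        self.EF_proc = np.asarray(self.EF_proc, dtype=float)
        if self.sigma_fuel is None:
            self.sigma_fuel = np.zeros_like(self.EF_fuel)
        if self.sigma_proc is None:
            self.sigma_proc = np.zeros_like(self.EF_proc)
        self.sigma_fuel = np.asarray(self.sigma_fuel, dtype=float)
        self.sigma_proc = np.asarray(self.sigma_proc, dtype=float)
        for name, arr in (
            ("EF_fuel", self.EF_fuel), ("EF_proc", self.EF_proc),
            ("sigma_fuel", self.sigma_fuel), ("sigma_proc", self.sigma_proc),
        ):
            if np.any(arr < 0):
                raise ValueError(f"negative entries in {name}")


@dataclass
class EmissionInventory:
    """Per-region, per-sector anthropogenic emissions plus a regional
    natural-source term (wildfire/deforestation; not sector-resolved)."""

    E: np.ndarray
    natural: np.ndarray
    species: str = "BaP"

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.natural = np.asarray(self.natural, dtype=float)
        if np.any(self.E < 0) or np.any(self.natural < 0):
            raise ValueError("emissions must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.E.shape[0]

    def region_totals(self) -> np.ndarray:
        return self.E.sum(axis=1)

    def total(self, include_natural: bool = True) -> float:
        t = float(self.E.sum())
        return t + float(self.natural.sum()) if include_natural else t


def _check_shapes(fa: FuelActivityTable, ef: EmissionFactorTable) -> None:
    if fa.FC.shape != ef.EF_fuel.shape:
        raise ValueError(
            f"fuel index sets disagree: FC {fa.FC.shape} vs EF_fuel {ef.EF_fuel.shape}"
        )
    if fa.AR.shape != ef.EF_proc.shape:
        raise ValueError(
            f"process index sets disagree: AR {fa.AR.shape} vs EF_proc {ef.EF_proc.shape}"
        )


def compute_emissions(
    fa: FuelActivityTable,
    ef: EmissionFactorTable,
    natural: np.ndarray | None = None,
) -> EmissionInventory:
    """Sum-of-products inventory: E = sum_k FC*EF_fuel + sum_p AR*EF_proc."""
    _check_shapes(fa, ef)
    E = (fa.FC * ef.EF_fuel).sum(axis=2) + (fa.AR * ef.EF_proc).sum(axis=2)
    nat = np.zeros(E.shape[0]) if natural is None else np.asarray(natural, dtype=float)
    return EmissionInventory(E=E, natural=nat, species=ef.species)


def monte_carlo_ci(
    fa: FuelActivityTable,
    ef: EmissionFactorTable,
    n_draws: int,
    seed: int,
    level: float = 0.95,
) -> dict:
    """Empirical central confidence interval of inventory aggregates.

    Each draw perturbs every emission factor by an independent lognormal
    multiplier exp(N(0, sigma)) (median 1) and recomputes the totals.
    Returns the central ``level`` interval for the global total and the
    per-region totals, plus the point estimate.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    _check_shapes(fa, ef)
    rng = np.random.default_rng(seed)
    mf = np.exp(rng.normal(0.0, 1.0, size=(n_draws, *ef.EF_fuel.shape)) * ef.sigma_fuel)
    mp = np.exp(rng.normal(0.0, 1.0, size=(n_draws, *ef.EF_proc.shape)) * ef.sigma_proc)
    region_totals = (
        (fa.FC * ef.EF_fuel * mf).sum(axis=(2, 3)) + (fa.AR * ef.EF_proc * mp).sum(axis=(2, 3))
    )
    totals = region_totals.sum(axis=1)
    alpha = (1.0 - level) / 2.0
    point = compute_emissions(fa, ef)
    return {
        "level": level,
        "point_total": float(point.E.sum()),
        "total": (float(np.quantile(totals, alpha)), float(np.quantile(totals, 1 - alpha))),
        "by_region": np.quantile(region_totals, [alpha, 1 - alpha], axis=0),
    }


def grid_emissions(
    inv: EmissionInventory,
    weights: RegionGrid,
    include_natural: bool = True,
    scenario: str = "base",
    year: int | None = None,
    region_totals: np.ndarray | None = None,
) -> GriddedEmissions:
    """Distribute regional totals onto the grid by the regional weights.

    ``region_totals`` overrides the inventory's anthropogenic region totals
    (used to grid scenario emission vectors); mass is conserved exactly.
    """
    weights.validate()
    anthro = inv.region_totals() if region_totals is None else np.asarray(region_totals, float)
    if anthro.shape != (weights.n_regions,):
        raise ValueError("one regional total per region required")
    totals = anthro + (inv.natural if include_natural else 0.0)
    values = np.tensordot(totals, weights.emission_weights, axes=(0, 0))
    return GriddedEmissions(values=values, species=inv.species, scenario=scenario, year=year)


def split_anthropogenic(inv: EmissionInventory) -> tuple[EmissionInventory, EmissionInventory]:
    """Separate the inventory into its anthropogenic and natural parts.

    Only the anthropogenic part enters the MRIO linkage (natural sources are
    not tied to economic activity); the natural part still contributes to
    the base concentration scenario.
    """
    anthro = replace(inv, E=inv.E.copy(), natural=np.zeros_like(inv.natural))
    natural = replace(inv, E=np.zeros_like(inv.E), natural=inv.natural.copy())
    return anthro, natural
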