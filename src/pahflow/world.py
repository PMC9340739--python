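"""Synthetic world generator.

Generates every input the pipeline consumes — a balanced multi-region
multi-sector economy, fuel/activity and emission-factor tables, spatial
weight and population grids, year-dependent transfer kernels, and regional
lung-cancer mortality series — with known structure embedded by
construction so that downstream stages have a recoverable ground truth:

* the economy is productive (spectral radius of the input-coefficient
  matrix well below 1) and exactly balanced;
* designated producer regions have high emission intensity and supply
  intermediates and final goods, while consumer regions have inflated final
  demand met largely by producer-origin goods, so consumer regions are net
  importers of embodied emissions by construction;
* every structural-decomposition factor (emission factors, energy
  efficiency, production structure, demand structure and level, population,
  transfer kernel, mortality) changes between years, so each driver has a
  nonzero true contribution.

The generator works from a small set of primitive factors per year (input
coefficients, demand shares and levels, population, emission and energy
intensities, kernel parameters, rates); every derived object (MRIO table,
inventory tables, mortality series) is a pure function of the primitives.
``perturb_factor`` edits one primitive and re-derives, which keeps all
balance invariants intact and makes single-driver experiments exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import RegionGrid, strip_region_mask
from .health import LIFETIME_YEARS, MortalitySeries, URRTable, WORLD_URR
from .inventory import EmissionFactorTable, EmissionInventory, FuelActivityTable, compute_emissions
from .mrio import MRIOTable
from .transport import TransferKernel

__all__ = [
    "WorldSpec",
    "YearSlice",
    "WorldBundle",
    "GenerationError",
    "FACTOR_NAMES",
    "generate_world",
    "perturb_factor",
    "single_driver_world",
]

FUEL_LABELS = ("coal", "natural_gas", "petroleum", "biomass")
PROCESS_LABELS = ("industrial_process",)

#: Factor names accepted by :func:`perturb_factor`.
FACTOR_NAMES = (
    "emission_factors",
    "energy_efficiency",
    "production_structure",
    "demand_structure",
    "demand_level",
    "population",
    "kernel",
    "mortality",
)

#: Mean base-year concentration the kernel amplitude is anchored to
#: (0.5 ng m^-3, a typical ambient annual-mean BaP level).
TARGET_MEAN_CONCENTRATION = 5e-4  # ug m^-3

NATURAL_SHARE = 0.175  # natural / anthropogenic regional emission ratio


class GenerationError(RuntimeError):
    """World generation failed to satisfy a structural constraint."""


@dataclass(frozen=True)
class WorldSpec:
    """Configuration of the synthetic world.

    The default world (4 regions x 5 sectors on an 18x36 grid over 2 years)
    is small enough for sub-second pipeline runs while still exercising
    multi-region aggregation; regions 0-1 are producer-heavy, 2-3
    consumer-heavy.
    """

    n_regions: int = 4
    n_sectors: int = 5
    grid_shape: tuple[int, int] = (18, 36)
    n_years: int = 2
    seed: int = 0
    producer_regions: tuple[int, ...] = (0, 1)
    consumer_regions: tuple[int, ...] = (2, 3)
    ef_sigma: float = 0.3
    demand_inflation: float = 4.0  # consumer vs producer per-capita demand
    pop_growth: float = 0.0  # per-year growth over the 70-year projection

    def validate(self) -> None:
        if self.n_regions < 2 or self.n_sectors < 2 or self.n_years < 2:
            raise ValueError("need at least 2 regions, 2 sectors and 2 years")
        prod, cons = set(self.producer_regions), set(self.consumer_regions)
        if prod & cons:
            raise ValueError("producer and consumer region sets must be disjoint")
        if not (prod | cons) <= set(range(self.n_regions)):
            raise ValueError("region roles reference unknown region indices")
        if self.ef_sigma < 0:
            raise ValueError("ef_sigma must be nonnegative")

    @property
    def n(self) -> int:
        return self.n_regions * self.n_sectors


@dataclass
class _Primitives:
    """Primitive factors of one year-slice; everything else is derived."""

    year: int
    A: np.ndarray  # (N, N) input coefficients
    demand_share: np.ndarray  # (N, R), columns sum to 1
    demand_pc: np.ndarray  # (R,) monetary final demand per person
    population: np.ndarray  # (R,) persons
    kfac: np.ndarray  # (N,) emissions per unit of energy/activity
    tfac: np.ndarray  # (N,) energy per unit of output
    fuel_shares: np.ndarray  # (K,), sums to 1
    fuel_relef: np.ndarray  # (K,), sum(shares * relef) == 1
    natural: np.ndarray  # (R,) natural-source emissions
    lr: np.ndarray  # (R,) lung-cancer rate per 100,000 per year
    kernel: TransferKernel

    def copy(self) -> "_Primitives":
        return replace(
            self,
            A=self.A.copy(), demand_share=self.demand_share.copy(),
            demand_pc=self.demand_pc.copy(), population=self.population.copy(),
            kfac=self.kfac.copy(), tfac=self.tfac.copy(),
            fuel_shares=self.fuel_shares.copy(), fuel_relef=self.fuel_relef.copy(),
            natural=self.natural.copy(), lr=self.lr.copy(),
        )


@dataclass
class YearSlice:
    """One model year: primitives plus the derived pipeline inputs."""

    primitives: _Primitives
    table: MRIOTable
    fuel_table: FuelActivityTable
    ef_table: EmissionFactorTable
    inventory: EmissionInventory
    mortality: MortalitySeries

    @property
    def year(self) -> int:
        return self.primitives.year

    @property
    def kernel(self) -> TransferKernel:
        return self.primitives.kernel

    @property
    def energy_use(self) -> np.ndarray:
        """Total energy/activity per sector-region (fuel plus process)."""
        return self.fuel_table.FC.sum(axis=2) + self.fuel_table.AR.sum(axis=2)


@dataclass
class WorldBundle:
    """Everything the pipeline needs, for every year."""

    spec: WorldSpec
    slices: list[YearSlice]
    grid: RegionGrid
    urr: URRTable = field(default_factory=lambda: URRTable(values={}, world_default=WORLD_URR))

    def __getitem__(self, year: int) -> YearSlice:
        return self.slices[year]

    @property
    def n_years(self) -> int:
        return len(self.slices)


def _smooth_weight_field(rng: np.random.Generator, mask: np.ndarray, n_regions: int) -> np.ndarray:
    """Smooth positive per-region fields, normalised to sum 1 per region."""
    shape = mask.shape
    weights = np.zeros((n_regions, *shape))
    for m in range(n_regions):
        raw = ndimage.gaussian_filter(rng.random(shape), sigma=1.5, mode="wrap") + 0.05
        raw = np.where(mask == m, raw, 0.0)
        weights[m] = raw / raw.sum()
    return weights


def _derive_slice(p: _Primitives, spec: WorldSpec) -> YearSlice:
    """Pure function primitives -> balanced year-slice."""
    R, S, N = spec.n_regions, spec.n_sectors, spec.n
    f_region = p.demand_pc * p.population
    Fd = p.demand_share * f_region[None, :]
    rho = float(np.abs(np.linalg.eigvals(p.A)).max())
    if rho >= 0.9:
        raise GenerationError(f"input-coefficient spectral radius {rho:.3f} >= 0.9")
    x = np.linalg.solve(np.eye(N) - p.A, Fd.sum(axis=1))
    Z = p.A * x[None, :]
    v = x - Z.sum(axis=0)
    if np.any(v < -1e-9 * max(1.0, x.max())):
        raise GenerationError("negative primary inputs: input-coefficient columns too heavy")
    table = MRIOTable(Z=Z, Fd=Fd, v=np.clip(v, 0.0, None), x=x,
                      n_regions=R, n_sectors=S)
    table.validate()

    energy = p.tfac * x  # combined fuel + process activity
    FC = (0.9 * energy)[:, None] * p.fuel_shares[None, :]
    AR = (0.1 * energy)[:, None]
    fuel_table = FuelActivityTable(
        FC=FC.reshape(R, S, -1), AR=AR.reshape(R, S, 1),
        fuel_labels=FUEL_LABELS, process_labels=PROCESS_LABELS,
    )
    EF_fuel = p.kfac[:, None] * p.fuel_relef[None, :]
    EF_proc = p.kfac[:, None]
    ef_table = EmissionFactorTable(
        EF_fuel=EF_fuel.reshape(R, S, -1), EF_proc=EF_proc.reshape(R, S, 1),
        sigma_fuel=np.full((R, S, len(FUEL_LABELS)), spec.ef_sigma),
        sigma_proc=np.full((R, S, 1), spec.ef_sigma),
    )
    inventory = compute_emissions(fuel_table, ef_table, natural=p.natural)

    growth = (1.0 + spec.pop_growth) ** np.arange(LIFETIME_YEARS)
    P = p.population[:, None] * growth[None, :]
    LR = np.repeat(p.lr[:, None], LIFETIME_YEARS, axis=1)
    mortality = MortalitySeries(LR=LR, P=P)
    return YearSlice(primitives=p, table=table, fuel_table=fuel_table,
                     ef_table=ef_table, inventory=inventory, mortality=mortality)


def _draw_input_coefficients(
    rng: np.random.Generator, spec: WorldSpec, max_attempts: int = 5
) -> np.ndarray:
    """Lognormal flow pattern rescaled column-wise; producers supply more."""
    N, S = spec.n, spec.n_sectors
    row_boost = np.ones(N)
    for m in spec.producer_regions:
        row_boost[m * S : (m + 1) * S] = 2.5
    for _ in range(max_attempts):
        raw = np.exp(rng.normal(0.0, 0.6, size=(N, N))) * row_boost[:, None]
        colsum_target = rng.uniform(0.35, 0.65, size=N)
        A = raw / raw.sum(axis=0, keepdims=True) * colsum_target[None, :]
        if np.abs(np.linalg.eigvals(A)).max() < 0.9:
            return A
    raise GenerationError("could not draw a productive input-coefficient matrix")


def generate_world(spec: WorldSpec) -> WorldBundle:
    """Deterministically generate a :class:`WorldBundle` from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R, S, N = spec.n_regions, spec.n_sectors, spec.n

    mask = strip_region_mask(spec.grid_shape, R)
    grid = RegionGrid(
        mask=mask,
        emission_weights=_smooth_weight_field(rng, mask, R),
        population_weights=_smooth_weight_field(rng, mask, R),
        lat=np.linspace(-90 + 90 / spec.grid_shape[0], 90 - 90 / spec.grid_shape[0], spec.grid_shape[0]),
        lon=np.linspace(-180 + 180 / spec.grid_shape[1], 180 - 180 / spec.grid_shape[1], spec.grid_shape[1]),
    )
    grid.validate()

    producer = np.isin(np.arange(R), spec.producer_regions)
    consumer = np.isin(np.arange(R), spec.consumer_regions)

    # --- year-0 primitives -------------------------------------------------
    A0 = _draw_input_coefficients(rng, spec)

    share_raw = np.exp(rng.normal(0.0, 0.5, size=(N, R)))
    producer_rows = np.repeat(producer, S)
    for n in range(R):
        if consumer[n]:  # consumer demand falls mostly on producer-origin goods
            share_raw[producer_rows, n] *= 4.0
    demand_share0 = share_raw / share_raw.sum(axis=0, keepdims=True)

    demand_pc0 = rng.uniform(0.8e-6, 1.6e-6, size=R)
    demand_pc0[consumer] *= spec.demand_inflation
    population0 = rng.uniform(3e7, 8e7, size=R)

    kfac0 = rng.uniform(0.15, 0.35, size=N)
    kfac0[np.repeat(producer, S)] = rng.uniform(0.8, 1.4, size=int(producer.sum()) * S)
    tfac0 = rng.uniform(0.3, 0.6, size=N)

    fuel_shares = rng.dirichlet(np.full(len(FUEL_LABELS), 4.0))
    relef_raw = rng.uniform(0.5, 1.5, size=len(FUEL_LABELS))
    fuel_relef = relef_raw / (fuel_shares @ relef_raw)

    lr0 = rng.uniform(15.0, 45.0, size=R)

    # provisional slice to anchor the kernel amplitude to a realistic
    # ambient level (mean base-year concentration ~0.5 ng/m3)
    provisional = _Primitives(
        year=0, A=A0, demand_share=demand_share0, demand_pc=demand_pc0,
        population=population0, kfac=kfac0, tfac=tfac0,
        fuel_shares=fuel_shares, fuel_relef=fuel_relef,
        natural=np.zeros(R), lr=lr0,
        kernel=TransferKernel(amplitude=1.0, year=0),
    )
    sl0 = _derive_slice(provisional, spec)
    anthro0 = sl0.inventory.region_totals()
    natural0 = NATURAL_SHARE * anthro0
    n_cells = spec.grid_shape[0] * spec.grid_shape[1]
    amp0 = TARGET_MEAN_CONCENTRATION * n_cells / (anthro0.sum() + natural0.sum())

    # --- per-year drifts: every decomposition factor moves -----------------
    slices: list[YearSlice] = []
    for y in range(spec.n_years):
        colsum0 = A0.sum(axis=0)
        col_jitter = np.exp(rng.normal(0.0, 0.04, size=N)) if y else np.ones(N)
        pat_jitter = np.exp(rng.normal(0.0, 0.05, size=(N, N))) if y else np.ones((N, N))
        raw = A0 * pat_jitter
        Ay = raw / raw.sum(axis=0, keepdims=True) * np.clip(colsum0 * col_jitter, 0.05, 0.8)[None, :]

        share_jitter = np.exp(rng.normal(0.0, 0.08, size=(N, R))) if y else np.ones((N, R))
        sraw = demand_share0 * share_jitter
        share_y = sraw / sraw.sum(axis=0, keepdims=True)

        p = _Primitives(
            year=y,
            A=Ay,
            demand_share=share_y,
            demand_pc=demand_pc0 * 1.05**y * (np.exp(rng.normal(0.0, 0.02, size=R)) if y else 1.0),
            population=population0 * 1.03**y,
            kfac=kfac0 * 0.92**y * (np.exp(rng.normal(0.0, 0.02, size=N)) if y else 1.0),
            tfac=tfac0 * 1.06**y,
            fuel_shares=fuel_shares,
            fuel_relef=fuel_relef,
            natural=natural0,
            lr=lr0 * 1.05**y,
            kernel=TransferKernel(
                sigma_lat=1.2, sigma_lon=1.8, shift_lon=1 + y,
                amplitude=amp0 * 1.08**y, year=y,
            ),
        )
        slices.append(_derive_slice(p, spec))

    return WorldBundle(spec=spec, slices=slices, grid=grid)


def perturb_factor(
    bundle: WorldBundle, factor_name: str, year: int, multiplier: float
) -> WorldBundle:
    """Return a copy of the bundle with one primitive factor of one year
    scaled, all derived quantities rebuilt and balance re-established.

    ``demand_structure`` applies a share-preserving power tilt (column
    shares raised to ``multiplier`` and renormalised) so that only the mix,
    never the level, of final demand changes.
    """
    if factor_name not in FACTOR_NAMES:
        raise ValueError(f"unknown factor {factor_name!r}; expected one of {FACTOR_NAMES}")
    if not 0 <= year < bundle.n_years:
        raise ValueError(f"year {year} outside 0..{bundle.n_years - 1}")
    p = bundle.slices[year].primitives.copy()
    if factor_name == "emission_factors":
        p.kfac = p.kfac * multiplier
    elif factor_name == "energy_efficiency":
        p.tfac = p.tfac * multiplier
    elif factor_name == "production_structure":
        p.A = p.A * multiplier
    elif factor_name == "demand_structure":
        tilted = p.demand_share**multiplier
        p.demand_share = tilted / tilted.sum(axis=0, keepdims=True)
    elif factor_name == "demand_level":
        p.demand_pc = p.demand_pc * multiplier
    elif factor_name == "population":
        p.population = p.population * multiplier
    elif factor_name == "kernel":
        p.kernel = replace(p.kernel, amplitude=p.kernel.amplitude * multiplier)
    elif factor_name == "mortality":
        p.lr = p.lr * multiplier
    new_slice = _derive_slice(p, bundle.spec)
    slices = list(bundle.slices)
    slices[year] = new_slice
    return WorldBundle(spec=bundle.spec, slices=slices, grid=bundle.grid, urr=bundle.urr)


def single_driver_world(
    bundle: WorldBundle, factor_name: str, multiplier: float, year: int = 1
) -> WorldBundle:
    """A world whose target year differs from year 0 in exactly one factor.

    Year ``year`` is replaced by a copy of year 0 with ``factor_name``
    scaled by ``multiplier``; all other years keep year-0 values.  This
    gives decomposition tests an exact single-driver ground truth.
    """
    p = bundle.slices[0].primitives.copy()
    p.year = year
    p.kernel = replace(p.kernel, year=year)
    slices = list(bundle.slices)
    slices[year] = _derive_slice(p, bundle.spec)
    cloned = WorldBundle(spec=bundle.spec, slices=slices, grid=bundle.grid, urr=bundle.urr)
    return perturb_factor(cloned, factor_name, year, multiplier)
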