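"""Structural decomposition of emission and burden changes.

Emission changes.  For each supply-chain perspective the sector-level
allocation matrix factorises into six socioeconomic drivers:

    income       Q_I = P  W  N  G  Teff K
    final sale   Q_S = K  Teff L  Zs S  P
    consumption  Q_C = K  Teff L  M  R  P

with K emission factors (emissions per unit energy), Teff energy efficiency
(energy per unit output), L / G the Leontief / Ghosh total-requirement
structure, N / Zs / M the primary-input / final-sale / consumption share
structures (columns, resp. region rows, summing to 1), W / S / R the
per-capita levels and P the population, all as conformable matrices whose
ordered product reproduces the perspective matrix.

The change between two years is attributed to each factor by the two-polar
decomposition: the average of the two polar elementary decompositions
(factors before the changed one taken at the start year and after it at the
end year, and vice versa), which is complete — contributions sum exactly to
the total change.  The average over all n! elementary orderings is provided
as a cross-check oracle.

Burden changes add two non-economic drivers: meteorology (transfer-kernel
year) and baseline lung-cancer mortality.  Each socioeconomic driver's
death contribution is evaluated by adding its emission change to the start
year and removing it from the end year (forward/backward control-variate
branches, averaged); the meteorology term swaps the kernel year at fixed
emissions, and the mortality term swaps the rate year at fixed exposure.
Because the dose-response is nonlinear, the burden decomposition does not
close exactly; the residual is reported, never re-allocated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import reduce

import numpy as np

from .grids import ConcentrationField
from .health import burden_from_concentration, lifetime_deaths
from .mrio import coefficient_set, sale_vector

__all__ = [
    "FactorSet",
    "DecompositionResult",
    "build_factors",
    "two_polar_sda",
    "full_average_sda",
    "health_driver_decomposition",
]

DECOMPOSABLE_PERSPECTIVES = ("income", "sale", "consumption")

FACTOR_ORDERS = {
    "income": ("population", "input_level", "input_structure", "production_structure",
               "energy_efficiency", "emission_factors"),
    "sale": ("emission_factors", "energy_efficiency", "production_structure",
             "sale_structure", "sale_level", "population"),
    "consumption": ("emission_factors", "energy_efficiency", "production_structure",
                    "demand_structure", "demand_level", "population"),
}


@dataclass
class FactorSet:
    """Ordered multiplicative factorisation of one perspective matrix."""

    perspective: str
    names: tuple[str, ...]
    factors: list[np.ndarray]
    n_regions: int
    n_sectors: int
    orientation: str  # "emit_rows" (N x R) or "emit_cols" (R x N)
    year: int | None = None

    def product(self, factors: list[np.ndarray] | None = None) -> np.ndarray:
        return reduce(np.matmul, factors if factors is not None else self.factors)

    @property
    def total(self) -> float:
        return float(self.product().sum())

    def emissions_by_region(self, matrix: np.ndarray | None = None) -> np.ndarray:
        """Collapse a sector-level perspective matrix to per-emitting-region mass."""
        Q = self.product() if matrix is None else matrix
        axis = 1 if self.orientation == "emit_rows" else 0
        per_sector = Q.sum(axis=axis)
        return per_sector.reshape(self.n_regions, self.n_sectors).sum(axis=1)


@dataclass
class DecompositionResult:
    """Per-factor contributions to a change, with an explicit residual."""

    target: str  # "emissions" | "deaths"
    perspective: str | None
    contributions: dict[str, float]
    residual: float
    delta_total: float
    endpoints: tuple[int, int]
    contribution_matrices: dict[str, np.ndarray] | None = None

    @property
    def attributed(self) -> float:
        return float(sum(self.contributions.values()))


def build_factors(year_slice, population: np.ndarray | None = None,
                  perspective: str = "consumption") -> FactorSet:
    """Factorise one balanced year-slice into the six drivers.

    ``year_slice`` needs a balanced MRIO table, an inventory and an energy
    table (fuel plus process activity); ``population`` defaults to the
    slice's base-year population.
    """
    if perspective not in DECOMPOSABLE_PERSPECTIVES:
        raise ValueError(f"perspective {perspective!r} has no six-factor form")
    t = year_slice.table
    R, S, N = t.n_regions, t.n_sectors, t.n
    pop = np.asarray(
        year_slice.mortality.P[:, 0] if population is None else population, dtype=float
    )
    if np.any(pop <= 0):
        raise ValueError("zero or negative population in a region")
    energy = np.asarray(year_slice.energy_use, dtype=float).ravel()
    E = year_slice.inventory.E.ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(energy > 0, E / energy, 0.0)
        Teff = np.where(t.x > 0, energy / t.x, 0.0)
    c = coefficient_set(t)

    def region_shares(vec: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
        totals = vec.reshape(R, S).sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError(f"zero total {what} in a region with nonzero flows")
        shares = vec / np.repeat(totals, S)
        return shares, totals

    if perspective == "consumption":
        f_region = t.Fd.sum(axis=0)
        if np.any(f_region <= 0):
            raise ValueError("zero total final demand in a region")
        M = t.Fd / f_region[None, :]
        r = f_region / pop
        factors = [np.diag(K), np.diag(Teff), c.L, M, np.diag(r), np.diag(pop)]
        orientation = "emit_rows"
    elif perspective == "sale":
        y = sale_vector(t)
        shares, totals = region_shares(y, "final sale")
        Zs = np.zeros((N, R))
        for m in range(R):
            Zs[m * S : (m + 1) * S, m] = shares[m * S : (m + 1) * S]
        s = totals / pop
        factors = [np.diag(K), np.diag(Teff), c.L, Zs, np.diag(s), np.diag(pop)]
        orientation = "emit_rows"
    else:  # income
        shares, totals = region_shares(t.v, "primary input")
        Ns = np.zeros((R, N))
        for m in range(R):
            Ns[m, m * S : (m + 1) * S] = shares[m * S : (m + 1) * S]
        w = totals / pop
        factors = [np.diag(pop), np.diag(w), Ns, c.G, np.diag(Teff), np.diag(K)]
        orientation = "emit_cols"
    return FactorSet(
        perspective=perspective, names=FACTOR_ORDERS[perspective], factors=factors,
        n_regions=R, n_sectors=S, orientation=orientation,
        year=getattr(year_slice, "year", None),
    )


def _chain(factors: list[np.ndarray]) -> np.ndarray | None:
    return reduce(np.matmul, factors) if factors else None


def _sandwich(pre: np.ndarray | None, mid: np.ndarray, suf: np.ndarray | None) -> np.ndarray:
    out = mid if pre is None else pre @ mid
    return out if suf is None else out @ suf


def _check_pair(f0: FactorSet, f1: FactorSet) -> None:
    if f0.perspective != f1.perspective or f0.names != f1.names:
        raise ValueError("factor sets are not comparable")
    for a, b in zip(f0.factors, f1.factors):
        if a.shape != b.shape:
            raise ValueError("factor shape mismatch between years")


def two_polar_sda(f0: FactorSet, f1: FactorSet) -> DecompositionResult:
    """Average of the two polar elementary decompositions; exactly complete."""
    _check_pair(f0, f1)
    mats: dict[str, np.ndarray] = {}
    for i, name in enumerate(f0.names):
        dF = f1.factors[i] - f0.factors[i]
        mats[name] = 0.5 * (
            _sandwich(_chain(f0.factors[:i]), dF, _chain(f1.factors[i + 1 :]))
            + _sandwich(_chain(f1.factors[:i]), dF, _chain(f0.factors[i + 1 :]))
        )
    delta = f1.total - f0.total
    contributions = {k: float(v.sum()) for k, v in mats.items()}
    return DecompositionResult(
        target="emissions", perspective=f0.perspective, contributions=contributions,
        residual=delta - sum(contributions.values()), delta_total=delta,
        endpoints=(f0.year or 0, f1.year if f1.year is not None else 1),
        contribution_matrices=mats,
    )


def full_average_sda(f0: FactorSet, f1: FactorSet, enumeration_limit: int = 7) -> DecompositionResult:
    """Arithmetic mean over all n! elementary decomposition orderings.

    Test oracle for :func:`two_polar_sda`; both are complete, and they
    coincide exactly for two factors.
    """
    _check_pair(f0, f1)
    n = len(f0.factors)
    if n > enumeration_limit:
        raise ValueError(f"{n}! orderings exceed the enumeration limit")
    mats = {name: np.zeros_like(np.asarray(f0.product(), dtype=float)) for name in f0.names}
    count = 0
    for order in itertools.permutations(range(n)):
        state = list(f0.factors)
        for idx in order:
            dF = f1.factors[idx] - f0.factors[idx]
            term = list(state)
            term[idx] = dF
            mats[f0.names[idx]] += reduce(np.matmul, term)
            state[idx] = f1.factors[idx]
        count += 1
    for name in mats:
        mats[name] /= count
    delta = f1.total - f0.total
    contributions = {k: float(v.sum()) for k, v in mats.items()}
    return DecompositionResult(
        target="emissions", perspective=f0.perspective, contributions=contributions,
        residual=delta - sum(contributions.values()), delta_total=delta,
        endpoints=(f0.year or 0, f1.year if f1.year is not None else 1),
        contribution_matrices=mats,
    )


def health_driver_decomposition(
    bundle,
    sda: DecompositionResult,
    f0: FactorSet,
    f1: FactorSet,
    year0: int = 0,
    year1: int = 1,
    dose_response: str = "exponential",
    kernel_mode: str = "per_year",
    mortality_mode: str = "per_year",
    mortality_ref: int = 0,
) -> DecompositionResult:
    """Decompose the change in lifetime deaths between two model years.

    Drivers: one term per socioeconomic factor of ``sda`` (emissions routed
    through the respective branch's kernel year), a meteorology term
    (kernel-year swap at fixed emissions) and a mortality term (rate-year
    swap at fixed exposure).  ``kernel_mode='fixed'`` / ``mortality_mode=
    'fixed'`` pin the respective input to the reference year, which together
    with ``dose_response='linear'`` makes the socioeconomic terms close
    exactly.
    """
    if sda.contribution_matrices is None:
        raise ValueError("SDA result lacks sector-level contribution matrices")
    if f0.perspective != sda.perspective:
        raise ValueError("factor sets and SDA result disagree on perspective")
    grid, urr = bundle.grid, bundle.urr
    s0, s1 = bundle[year0], bundle[year1]
    k0 = s0.kernel
    kt = k0 if kernel_mode == "fixed" else s1.kernel
    ms_ref = bundle[mortality_ref].mortality
    ms0 = ms_ref if mortality_mode == "fixed" else s0.mortality
    mst = ms_ref if mortality_mode == "fixed" else s1.mortality

    E0 = s0.inventory.region_totals()
    Et = s1.inventory.region_totals()
    natural = s0.inventory.natural  # held fixed: not tied to economic activity

    def concentration(kernel, regional_anthro):
        em = np.tensordot(np.clip(regional_anthro, 0.0, None) + natural,
                          grid.emission_weights, axes=(0, 0))
        return ConcentrationField(kernel.apply(em), year=kernel.year)

    def deaths(kernel, regional_anthro, ms) -> float:
        b = burden_from_concentration(concentration(kernel, regional_anthro), urr, ms, grid,
                                      dose_response=dose_response)
        return float(b.regional.sum())

    contributions: dict[str, float] = {}
    for name in sda.contributions:
        dq = f0.emissions_by_region(sda.contribution_matrices[name])
        forward = deaths(k0, E0 + dq, ms_ref) - deaths(k0, E0, ms_ref)
        backward = deaths(kt, Et, ms_ref) - deaths(kt, Et - dq, ms_ref)
        contributions[name] = 0.5 * (forward + backward)

    d_mc = 0.5 * (
        (deaths(kt, E0, ms_ref) - deaths(k0, E0, ms_ref))
        + (deaths(kt, Et, ms_ref) - deaths(k0, Et, ms_ref))
    )
    contributions["meteorology"] = d_mc

    paf0 = burden_from_concentration(concentration(k0, E0), urr, ms_ref, grid,
                                     dose_response=dose_response).paf
    paft = burden_from_concentration(concentration(kt, Et), urr, ms_ref, grid,
                                     dose_response=dose_response).paf

    def deaths_from_paf(paf_grid, ms) -> float:
        return float(lifetime_deaths(paf_grid, ms, grid).regional.sum())

    d_ld = 0.5 * (
        (deaths_from_paf(paf0, mst) - deaths_from_paf(paf0, ms0))
        + (deaths_from_paf(paft, mst) - deaths_from_paf(paft, ms0))
    )
    contributions["mortality"] = d_ld

    delta_total = deaths(kt, Et, mst) - deaths(k0, E0, ms0)
    residual = delta_total - sum(contributions.values())
    return DecompositionResult(
        target="deaths", perspective=sda.perspective, contributions=contributions,
        residual=residual, delta_total=delta_total, endpoints=(year0, year1),
    )
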