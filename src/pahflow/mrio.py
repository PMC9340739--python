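"""Environmentally extended multi-regional input-output (EE-MRIO) accounting.

A multi-regional input-output table records, for ``R`` regions with ``S``
sectors each (``N = R*S`` sector-region pairs, region-major order):

* ``Z``  (N, N)  intermediate monetary flows z_ij^mn from sector i in
  region m (row) to sector j in region n (column),
* ``Fd`` (N, R)  final demand f_i^mn of destination region n (column) for
  products of sector i in region m (row),
* ``v``  (N,)    primary inputs v_j^n (value added, one per column sector),
* ``x``  (N,)    total output x_i^m.

The table is balanced when

    x_i^m = sum_{n,j} z_ij^mn + sum_n f_i^mn      (row balance)
    x_j^n = sum_{m,i} z_ij^mn + v_j^n             (column balance)

Direct input coefficients a_ij^mn = z_ij^mn / x_j^n define the Leontief
inverse L = (I - A)^-1; direct output coefficients b_ij^mn = z_ij^mn / x_i^m
define the Ghosh inverse G = (I - B)^-1.  Linking an emission inventory
through the emission intensity u_i^m = E_i^m / x_i^m, the same emitted mass
is allocated along the supply chain to four perspectives:

    production   diag blocks of E itself (who emits),
    income       Q_I = V G U   (who supplied the primary inputs),
    final sale   Q_S = U L Y   (who sold the final products),
    consumption  Q_C = U L F   (who finally consumed).

All four perspectives conserve the total anthropogenic emitted mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MRIOTable",
    "CoefficientSet",
    "PerspectiveEmissions",
    "NetFlowResult",
    "NonProductiveEconomyError",
    "input_coefficients",
    "output_coefficients",
    "leontief_inverse",
    "ghosh_inverse",
    "coefficient_set",
    "emission_intensity",
    "sale_vector",
    "production_based",
    "income_based",
    "sale_based",
    "consumption_based",
    "four_perspectives",
    "aggregate_regions",
    "net_flows",
    "deflate",
]

PERSPECTIVES = ("income", "production", "sale", "consumption")

BALANCE_RTOL = 1e-8


class NonProductiveEconomyError(ValueError):
    """Spectral radius of the coefficient matrix is >= 1: the Leontief /
    Ghosh series does not converge and the economy cannot meet any demand."""


@dataclass
class MRIOTable:
    """Balanced multi-region, multi-sector input-output table."""

    Z: np.ndarray
    Fd: np.ndarray
    v: np.ndarray
    x: np.ndarray
    n_regions: int
    n_sectors: int
    deflators: np.ndarray | None = None
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        self.Fd = np.asarray(self.Fd, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if not self.region_labels:
            self.region_labels = [f"R{m}" for m in range(self.n_regions)]

    @property
    def n(self) -> int:
        return self.n_regions * self.n_sectors

    def validate(self, rtol: float = BALANCE_RTOL) -> None:
        """Check shapes, nonnegativity and both balance identities."""
        N, R = self.n, self.n_regions
        if self.Z.shape != (N, N) or self.Fd.shape != (N, R):
            raise ValueError("inconsistent MRIO block shapes")
        if self.v.shape != (N,) or self.x.shape != (N,):
            raise ValueError("v and x must have one entry per sector-region")
        for name, arr in (("Z", self.Z), ("Fd", self.Fd), ("v", self.v), ("x", self.x)):
            if np.any(arr < -rtol * max(1.0, np.abs(arr).max(initial=0.0))):
                raise ValueError(f"negative entries in {name}")
        scale = max(self.x.max(initial=0.0), 1.0)
        row = self.Z.sum(axis=1) + self.Fd.sum(axis=1)
        col = self.Z.sum(axis=0) + self.v
        if np.abs(row - self.x).max() > rtol * scale:
            raise ValueError("row balance violated: x != Z.sum(1) + Fd.sum(1)")
        if np.abs(col - self.x).max() > rtol * scale:
            raise ValueError("column balance violated: x != Z.sum(0) + v")

    def copy(self) -> "MRIOTable":
        return replace(
            self,
            Z=self.Z.copy(),
            Fd=self.Fd.copy(),
            v=self.v.copy(),
            x=self.x.copy(),
            deflators=None if self.deflators is None else np.asarray(self.deflators).copy(),
            region_labels=list(self.region_labels),
        )


@dataclass
class CoefficientSet:
    """Direct coefficients and their total-requirement inverses."""

    A: np.ndarray
    B: np.ndarray
    L: np.ndarray
    G: np.ndarray


@dataclass
class PerspectiveEmissions:
    """Region-of-emission x region-of-driver allocation of emitted mass.

    ``Qmat[m, n]`` is the mass emitted in region m attributable to region n's
    driver (primary input, production, final sale or final consumption).
    ``sector`` keeps the pre-aggregation sector-level matrix: orientation
    ``(N, R)`` for sale/consumption/production (emitting sector-region rows)
    and ``(R, N)`` for income (driving region rows, emitting columns).
    """

    perspective: str
    Qmat: np.ndarray
    region_labels: list[str]
    sector: np.ndarray | None = None

    def __post_init__(self):
        if self.perspective not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {self.perspective!r}")

    @property
    def total(self) -> float:
        return float(self.Qmat.sum())

    def emitted_by_region(self) -> np.ndarray:
        """Mass emitted inside each region (row sums)."""
        return self.Qmat.sum(axis=1)

    def driven_by_region(self) -> np.ndarray:
        """Mass each region's driver causes anywhere (column sums)."""
        return self.Qmat.sum(axis=0)


def _region_sum(values: np.ndarray, n_regions: int, n_sectors: int, axis: int) -> np.ndarray:
    """Sum an array over the sector dimension of one region-major axis."""
    shape = list(values.shape)
    shape[axis : axis + 1] = [n_regions, n_sectors]
    return values.reshape(shape).sum(axis=axis + 1)


def input_coefficients(t: MRIOTable) -> np.ndarray:
    """Direct input coefficients a_ij^mn = z_ij^mn / x_j^n.

    Columns with zero total output are set to zero: empty sectors are a
    feature of real-world tables, not an error.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(t.x[None, :] > 0, t.Z / t.x[None, :], 0.0)
    return A


def output_coefficients(t: MRIOTable) -> np.ndarray:
    """Direct output coefficients b_ij^mn = z_ij^mn / x_i^m (row division)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.where(t.x[:, None] > 0, t.Z / t.x[:, None], 0.0)
    return B


def _total_requirements(C: np.ndarray, name: str) -> np.ndarray:
    n = C.shape[0]
    rho = np.abs(np.linalg.eigvals(C)).max() if n else 0.0
    if rho >= 1.0:
        raise NonProductiveEconomyError(
            f"spectral radius of {name} is {rho:.6f} >= 1; economy is not productive"
        )
    return np.linalg.solve(np.eye(n) - C, np.eye(n))


def leontief_inverse(A: np.ndarray) -> np.ndarray:
    """L = (I - A)^-1 via direct solve; requires spectral radius < 1."""
    return _total_requirements(np.asarray(A, dtype=float), "A")


def ghosh_inverse(B: np.ndarray) -> np.ndarray:
    """G = (I - B)^-1 via direct solve; requires spectral radius < 1."""
    return _total_requirements(np.asarray(B, dtype=float), "B")


def coefficient_set(t: MRIOTable) -> CoefficientSet:
    A = input_coefficients(t)
    B = output_coefficients(t)
    return CoefficientSet(A=A, B=B, L=leontief_inverse(A), G=ghosh_inverse(B))


def emission_intensity(E: np.ndarray, x: np.ndarray) -> np.ndarray:
    """u_i^m = E_i^m / x_i^m, zero where output is zero."""
    E = np.asarray(E, dtype=float).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(x > 0, E / x, 0.0)


def sale_vector(t: MRIOTable) -> np.ndarray:
    """y_i^m = sum_n f_i^mn: final products sold to all destinations."""
    return t.Fd.sum(axis=1)


def production_based(
    E: np.ndarray, n_regions: int, n_sectors: int, region_labels: list[str] | None = None
) -> PerspectiveEmissions:
    """Diagonal allocation: each region drives exactly its own emissions."""
    E = np.asarray(E, dtype=float).ravel()
    e_region = _region_sum(E, n_regions, n_sectors, axis=0)
    sector = np.zeros((E.size, n_regions))
    for m in range(n_regions):
        sector[m * n_sectors : (m + 1) * n_sectors, m] = E[m * n_sectors : (m + 1) * n_sectors]
    labels = region_labels or [f"R{m}" for m in range(n_regions)]
    return PerspectiveEmissions("production", np.diag(e_region), labels, sector=sector)


def income_based(
    v: np.ndarray, G: np.ndarray, u: np.ndarray, n_regions: int, n_sectors: int,
    region_labels: list[str] | None = None,
) -> PerspectiveEmissions:
    """Q_I = V (I-B)^-1 U: emissions enabled by each region's primary inputs.

    Row index carries the driving (income-receiving) sector-region, column
    index the emitting sector-region; ``Qmat`` is re-oriented to the common
    emitting-row / driving-column convention.
    """
    Q = (np.asarray(v, float)[:, None] * G) * np.asarray(u, float)[None, :]
    by_driver_emitter = _region_sum(_region_sum(Q, n_regions, n_sectors, 0), n_regions, n_sectors, 1)
    labels = region_labels or [f"R{m}" for m in range(n_regions)]
    sector = _region_sum(Q, n_regions, n_sectors, 0)  # (R driver, N emitter)
    return PerspectiveEmissions("income", by_driver_emitter.T, labels, sector=sector)


def sale_based(
    u: np.ndarray, L: np.ndarray, y: np.ndarray, n_regions: int, n_sectors: int,
    region_labels: list[str] | None = None,
) -> PerspectiveEmissions:
    """Q_S = U (I-A)^-1 Y: emissions embodied in each region's final sales."""
    Q = (np.asarray(u, float)[:, None] * L) * np.asarray(y, float)[None, :]
    Qmat = _region_sum(_region_sum(Q, n_regions, n_sectors, 0), n_regions, n_sectors, 1)
    labels = region_labels or [f"R{m}" for m in range(n_regions)]
    sector = _region_sum(Q, n_regions, n_sectors, 1)  # (N emitter, R driver)
    return PerspectiveEmissions("sale", Qmat, labels, sector=sector)


def consumption_based(
    u: np.ndarray, L: np.ndarray, Fd: np.ndarray, n_regions: int, n_sectors: int,
    region_labels: list[str] | None = None,
) -> PerspectiveEmissions:
    """Q_C = U (I-A)^-1 F: emissions embodied in each region's consumption."""
    Q = np.asarray(u, float)[:, None] * (L @ np.asarray(Fd, float))  # (N, R)
    Qmat = _region_sum(Q, n_regions, n_sectors, 0)
    labels = region_labels or [f"R{m}" for m in range(n_regions)]
    return PerspectiveEmissions("consumption", Qmat, labels, sector=Q)


def four_perspectives(
    t: MRIOTable, E: np.ndarray, coeffs: CoefficientSet | None = None
) -> dict[str, PerspectiveEmissions]:
    """All four allocations of the anthropogenic inventory ``E`` (R, S)."""
    c = coeffs or coefficient_set(t)
    u = emission_intensity(E, t.x)
    R, S = t.n_regions, t.n_sectors
    return {
        "production": production_based(E, R, S, t.region_labels),
        "income": income_based(t.v, c.G, u, R, S, t.region_labels),
        "sale": sale_based(u, c.L, sale_vector(t), R, S, t.region_labels),
        "consumption": consumption_based(u, c.L, t.Fd, R, S, t.region_labels),
    }


def aggregate_regions(Q: PerspectiveEmissions, mapping: dict[int, int]) -> PerspectiveEmissions:
    """Block-sum a perspective matrix into macro-regions.

    ``mapping`` sends every source-region index to a macro-region index; it
    must be total over the regions of ``Q``.
    """
    R = Q.Qmat.shape[0]
    missing = [m for m in range(R) if m not in mapping]
    if missing:
        raise ValueError(f"regions without macro-region mapping: {missing}")
    macros = sorted(set(mapping.values()))
    idx = {g: k for k, g in enumerate(macros)}
    out = np.zeros((len(macros), len(macros)))
    for m in range(R):
        for n in range(R):
            out[idx[mapping[m]], idx[mapping[n]]] += Q.Qmat[m, n]
    labels = [f"M{g}" for g in macros]
    return PerspectiveEmissions(Q.perspective, out, labels)


@dataclass
class NetFlowResult:
    """Pairwise net transfers of embodied emissions between regions.

    ``netflow[m, n] = Qmat[m, n] - Qmat[n, m]``: mass emitted in m for n's
    driver minus the reverse.  A region is a net importer when the burden its
    driver causes in other regions exceeds the burden it suffers from other
    regions' drivers (positive net position as a driver).
    """

    netflow: np.ndarray
    net_position: np.ndarray
    importers: list[int]
    exporters: list[int]
    total_net_inflow: float
    total_net_position: float
    region_labels: list[str]


def net_flows(Q: PerspectiveEmissions) -> NetFlowResult:
    Qm = Q.Qmat
    if Qm.shape[0] != Qm.shape[1]:
        raise ValueError("net flows require a square region-by-region matrix")
    netflow = Qm - Qm.T
    # net position of region n as a driver: sum over emitting regions m != n
    position = netflow.sum(axis=0)
    importers = [int(n) for n in np.nonzero(position > 0)[0]]
    exporters = [int(n) for n in np.nonzero(position < 0)[0]]
    total_net_inflow = float(netflow[netflow > 0].sum())
    total_net_position = float(position[position > 0].sum())
    return NetFlowResult(
        netflow=netflow,
        net_position=position,
        importers=importers,
        exporters=exporters,
        total_net_inflow=total_net_inflow,
        total_net_position=total_net_position,
        region_labels=list(Q.region_labels),
    )


def deflate(t: MRIOTable, base_year_deflators: np.ndarray) -> MRIOTable:
    """Convert a nominal table to constant prices of the base year.

    Every monetary flow is deflated by the price index of its origin region
    (the region producing the goods): rows of ``Z`` and ``Fd`` and the output
    vector ``x`` are divided by the origin deflator, and the primary-input
    row is recomputed as the column-balance residual so that the deflated
    table satisfies both balance identities.
    """
    d = np.asarray(base_year_deflators, dtype=float)
    if d.shape != (t.n_regions,):
        raise ValueError("one deflator per region required")
    if np.any(d <= 0):
        raise ValueError("deflators must be strictly positive")
    drow = np.repeat(d, t.n_sectors)
    Z = t.Z / drow[:, None]
    Fd = t.Fd / drow[:, None]
    x = t.x / drow
    v = x - Z.sum(axis=0)
    if np.any(v < -BALANCE_RTOL * max(1.0, x.max(initial=0.0))):
        raise ValueError("deflation produced negative primary inputs")
    out = MRIOTable(
        Z=Z, Fd=Fd, v=np.clip(v, 0.0, None), x=x,
        n_regions=t.n_regions, n_sectors=t.n_sectors,
        deflators=np.ones_like(d), region_labels=list(t.region_labels),
    )
    out.validate()
    return out
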