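"""On-disk formats: MRIO block CSV, long-format tables, NetCDF grids.

The MRIO layout mirrors the conventional block arrangement: two header
rows (region, sector) for the columns, one row per producing sector-region
carrying its Z block, final-demand block and total output, and a trailing
primary-input row.  Floats are written with 17 significant digits so a
write/read cycle is bit-exact.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import ConcentrationField, GriddedEmissions, RegionGrid
from .health import MortalitySeries
from .inventory import EmissionFactorTable, FuelActivityTable
from .mrio import MRIOTable, PerspectiveEmissions

__all__ = [
    "write_mrio_csv", "read_mrio_csv",
    "write_fuel_activity_csv", "read_fuel_activity_csv",
    "write_emission_factors_csv", "read_emission_factors_csv",
    "write_mortality_csv", "read_mortality_csv",
    "write_perspective_csv",
    "write_grid_netcdf", "read_grid_netcdf",
    "write_region_grid_netcdf", "read_region_grid_netcdf",
    "write_json",
]


def _fmt(value: float) -> str:
    return format(float(value), ".17g")


def write_mrio_csv(t: MRIOTable, path: str | Path) -> None:
    R, S, N = t.n_regions, t.n_sectors, t.n
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["#meta", "n_regions", R, "n_sectors", S])
        w.writerow(["region", ""] + [t.region_labels[j // S] for j in range(N)]
                   + [f"fd:{lab}" for lab in t.region_labels] + ["x"])
        w.writerow(["sector", ""] + [f"S{j % S}" for j in range(N)] + [""] * R + [""])
        for i in range(N):
            w.writerow(
                [t.region_labels[i // S], f"S{i % S}"]
                + [_fmt(z) for z in t.Z[i]]
                + [_fmt(f) for f in t.Fd[i]]
                + [_fmt(t.x[i])]
            )
        w.writerow(["v", ""] + [_fmt(val) for val in t.v] + [""] * R + [""])


def read_mrio_csv(path: str | Path) -> MRIOTable:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    meta = rows[0]
    R, S = int(meta[2]), int(meta[4])
    N = R * S
    region_labels = rows[1][2 : 2 + N : S]
    body = rows[3 : 3 + N]
    Z = np.array([[float(c) for c in row[2 : 2 + N]] for row in body])
    Fd = np.array([[float(c) for c in row[2 + N : 2 + N + R]] for row in body])
    x = np.array([float(row[2 + N + R]) for row in body])
    v = np.array([float(c) for c in rows[3 + N][2 : 2 + N]])
    return MRIOTable(Z=Z, Fd=Fd, v=v, x=x, n_regions=R, n_sectors=S,
                     region_labels=list(region_labels))


def _long_frame(values: np.ndarray, kind: str, labels: tuple[str, ...]) -> pd.DataFrame:
    R, S, K = values.shape
    reg, sec, src = np.meshgrid(np.arange(R), np.arange(S), np.arange(K), indexing="ij")
    return pd.DataFrame({
        "region": reg.ravel(), "sector": sec.ravel(), "kind": kind,
        "source": [labels[k] for k in src.ravel()], "value": values.ravel(),
    })


def write_fuel_activity_csv(fa: FuelActivityTable, path: str | Path) -> None:
    df = pd.concat([
        _long_frame(fa.FC, "fuel", fa.fuel_labels),
        _long_frame(fa.AR, "process", fa.process_labels),
    ])
    df.to_csv(path, index=False, float_format="%.17g")


def read_fuel_activity_csv(path: str | Path) -> FuelActivityTable:
    df = pd.read_csv(path, float_precision="round_trip")

    def block(kind: str) -> tuple[np.ndarray, tuple[str, ...]]:
        sub = df[df["kind"] == kind]
        labels = tuple(dict.fromkeys(sub["source"]))
        R, S = sub["region"].max() + 1, sub["sector"].max() + 1
        arr = np.zeros((R, S, len(labels)))
        src_idx = {s: k for k, s in enumerate(labels)}
        arr[sub["region"], sub["sector"], [src_idx[s] for s in sub["source"]]] = sub["value"]
        return arr, labels

    FC, fuels = block("fuel")
    AR, procs = block("process")
    return FuelActivityTable(FC=FC, AR=AR, fuel_labels=fuels, process_labels=procs)


def write_emission_factors_csv(ef: EmissionFactorTable, path: str | Path) -> None:
    R, S, K = ef.EF_fuel.shape
    P = ef.EF_proc.shape[2]
    fuel = _long_frame(ef.EF_fuel, "fuel", tuple(f"fuel{k}" for k in range(K)))
    fuel["sigma"] = ef.sigma_fuel.ravel()
    proc = _long_frame(ef.EF_proc, "process", tuple(f"proc{p}" for p in range(P)))
    proc["sigma"] = ef.sigma_proc.ravel()
    out = pd.concat([fuel, proc])
    out["species"] = ef.species
    out.to_csv(path, index=False, float_format="%.17g")


def read_emission_factors_csv(path: str | Path) -> EmissionFactorTable:
    df = pd.read_csv(path, float_precision="round_trip")

    def block(kind: str) -> tuple[np.ndarray, np.ndarray]:
        sub = df[df["kind"] == kind]
        labels = tuple(dict.fromkeys(sub["source"]))
        R, S = sub["region"].max() + 1, sub["sector"].max() + 1
        ef = np.zeros((R, S, len(labels)))
        sg = np.zeros_like(ef)
        src_idx = {s: k for k, s in enumerate(labels)}
        cols = [src_idx[s] for s in sub["source"]]
        ef[sub["region"], sub["sector"], cols] = sub["value"]
        sg[sub["region"], sub["sector"], cols] = sub["sigma"]
        return ef, sg

    EF_fuel, sigma_fuel = block("fuel")
    EF_proc, sigma_proc = block("process")
    return EmissionFactorTable(EF_fuel=EF_fuel, EF_proc=EF_proc,
                               sigma_fuel=sigma_fuel, sigma_proc=sigma_proc,
                               species=str(df["species"].iloc[0]))


def write_mortality_csv(ms: MortalitySeries, path: str | Path) -> None:
    R, Y = ms.LR.shape
    reg, yr = np.meshgrid(np.arange(R), np.arange(Y), indexing="ij")
    pd.DataFrame({
        "region": reg.ravel(), "year": yr.ravel(),
        "rate_per_100k": ms.LR.ravel(), "population": ms.P.ravel(),
    }).to_csv(path, index=False, float_format="%.17g")


def read_mortality_csv(path: str | Path) -> MortalitySeries:
    df = pd.read_csv(path, float_precision="round_trip")
    R, Y = df["region"].max() + 1, df["year"].max() + 1
    LR = np.zeros((R, Y))
    P = np.zeros((R, Y))
    LR[df["region"], df["year"]] = df["rate_per_100k"]
    P[df["region"], df["year"]] = df["population"]
    return MortalitySeries(LR=LR, P=P)


def write_perspective_csv(q: PerspectiveEmissions, path: str | Path) -> None:
    pd.DataFrame(q.Qmat, index=q.region_labels, columns=q.region_labels).to_csv(
        path, float_format="%.17g", index_label=f"emitting\\driving[{q.perspective}]"
    )


def _to_dataset(values: np.ndarray, attrs: dict) -> xr.Dataset:
    n_lat, n_lon = values.shape
    return xr.Dataset(
        {"values": (("lat", "lon"), values)},
        coords={
            "lat": np.linspace(-90 + 90 / n_lat, 90 - 90 / n_lat, n_lat),
            "lon": np.linspace(-180 + 180 / n_lon, 180 - 180 / n_lon, n_lon),
        },
        attrs=attrs,
    )


def write_grid_netcdf(field: GriddedEmissions | ConcentrationField, path: str | Path) -> None:
    kind = "emissions" if isinstance(field, GriddedEmissions) else "concentration"
    attrs = {"kind": kind, "species": field.species, "scenario": field.scenario,
             "year": -1 if field.year is None else int(field.year)}
    _to_dataset(field.values, attrs).to_netcdf(path, engine="scipy")


def read_grid_netcdf(path: str | Path) -> GriddedEmissions | ConcentrationField:
    with xr.open_dataset(path, engine="scipy") as ds:
        values = ds["values"].values.copy()
        attrs = dict(ds.attrs)
    year = None if attrs.get("year", -1) == -1 else int(attrs["year"])
    cls = GriddedEmissions if attrs.get("kind") == "emissions" else ConcentrationField
    return cls(values=values, species=attrs.get("species", "BaP"),
               scenario=attrs.get("scenario", "base"), year=year)


def write_region_grid_netcdf(grid: RegionGrid, path: str | Path) -> None:
    R = grid.n_regions
    n_lat, n_lon = grid.shape
    ds = xr.Dataset(
        {
            "region_mask": (("lat", "lon"), grid.mask.astype(np.int32)),
            "emission_weights": (("region", "lat", "lon"), grid.emission_weights),
            "population_weights": (("region", "lat", "lon"), grid.population_weights),
        },
        coords={
            "region": np.arange(R),
            "lat": grid.lat if grid.lat is not None else np.arange(n_lat, dtype=float),
            "lon": grid.lon if grid.lon is not None else np.arange(n_lon, dtype=float),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_region_grid_netcdf(path: str | Path) -> RegionGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        grid = RegionGrid(
            mask=ds["region_mask"].values.astype(np.int64),
            emission_weights=ds["emission_weights"].values.copy(),
            population_weights=ds["population_weights"].values.copy(),
            lat=ds["lat"].values.copy(),
            lon=ds["lon"].values.copy(),
        )
    return grid


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
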