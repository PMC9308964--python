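"""Carbon-stock accounting: concentrations → kg C m⁻² → zonal and global Pg C.

A fixed-depth topsoil (0–30 cm) stock is

    stock [kg C m⁻²] = (oc% / 100) · BD [g cm⁻³ = t m⁻³] · 1000 · depth [m]

with bulk density supplied by the pedotransfer function evaluated at each
percentile's own carbon content (richer soil is lighter, so the same
concentration gap translates into a smaller stock gap than a fixed-BD
calculation would suggest; a switch allows fixed-BD accounting for
sensitivity checks). Zone totals convert with 1 kg m⁻² × 10⁶ km² = 1 Pg.

The published ecoregion-level cropland stock table ships as a CSV fixture so
the global accounting arithmetic (additional potentials, ecoregion shares)
can be recomputed without the global rasters.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ptf import GLOBAL_PTF, evaluate_ptf, oc_pct_to_gkg

KG_M2_KM2_TO_PG = 1e-6  # 1 kg m⁻² over 1 km² = 1e6 kg = 1e-6 Pg
DEFAULT_DEPTH_M = 0.3
QUANTILE_VARS = ("q50", "q75", "q90")


def cell_stock(oc_pct, bd_gcm3, depth_m: float = DEFAULT_DEPTH_M) -> np.ndarray:
    """Areal carbon stock (kg C m⁻²) of one layer."""
    oc = np.asarray(oc_pct, dtype=float)
    bd = np.asarray(bd_gcm3, dtype=float)
    if np.any(oc < 0) or np.any(bd <= 0) or depth_m <= 0:
        raise ValueError("need oc >= 0, bd > 0, depth > 0")
    return (oc / 100.0) * (bd * 1000.0) * depth_m


def stock_grid(quantiles, depth_m: float = DEFAULT_DEPTH_M, ptf=GLOBAL_PTF,
               fixed_bd: float | None = None):
    """Per-cell stocks (kg C m⁻²) for each percentile of a quantile Dataset.

    ``fixed_bd`` bypasses the PTF with a constant bulk density (sensitivity
    mode); otherwise BD is re-evaluated at each percentile's own oc.
    """
    import xarray as xr

    out = {}
    for var in quantiles.data_vars:
        oc = quantiles[var].values
        bd = fixed_bd if fixed_bd is not None else evaluate_ptf(oc_pct_to_gkg(oc), ptf)
        out[var] = (quantiles[var].dims, cell_stock(oc, bd, depth_m))
    return xr.Dataset(out, coords=quantiles.coords)


@dataclass
class ZoneReport:
    """Per-zone and global stock totals (Pg C) with additional potentials."""

    table: pd.DataFrame  # index zone, columns q50_pg/q75_pg/q90_pg/area_km2

    @property
    def global_total(self) -> pd.Series:
        return self.table[[f"{q}_pg" for q in QUANTILE_VARS] + ["area_km2"]].sum()

    def potential(self, level: str = "q75") -> float:
        """Global additional potential (Pg C): level total − q50 total."""
        g = self.global_total
        return float(g[f"{level}_pg"] - g["q50_pg"])

    def zone_potentials(self, level: str = "q75") -> pd.Series:
        return self.table[f"{level}_pg"] - self.table["q50_pg"]


def aggregate(stocks, area_km2, zone, mask=None, zone_names=None) -> ZoneReport:
    """Sum per-cell stocks to zone and global Pg C totals.

    ``stocks``: Dataset of kg m⁻² per percentile; ``area_km2``/``zone``/
    ``mask`` are aligned 2-D arrays (mask True = include).
    """
    area = np.asarray(area_km2, dtype=float)
    if area.shape != np.asarray(zone).shape:
        raise ValueError("area and zone layers must align")
    zones = np.asarray(zone).ravel()
    keep = (np.ones(zones.shape, dtype=bool) if mask is None
            else np.asarray(mask).ravel().astype(bool))
    rows = {}
    zone_ids = np.unique(zones[keep])
    for zid in zone_ids:
        sel = keep & (zones == zid)
        row = {
            f"{var}_pg": float(
                np.sum(stocks[var].values.ravel()[sel] * area.ravel()[sel])
            ) * KG_M2_KM2_TO_PG
            for var in stocks.data_vars
        }
        row["area_km2"] = float(area.ravel()[sel].sum())
        name = zone_names[zid] if zone_names is not None else zid
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "zone"
    return ZoneReport(table)


def load_table1() -> ZoneReport:
    """The packaged ecoregion-level cropland stock table (Pg C by percentile)."""
    ref = importlib.resources.files("socquant.data") / "table1_ecoregions.csv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path).set_index("ecoregion")
    table.index.name = "zone"
    return ZoneReport(table)


def additional_potential(report: ZoneReport) -> pd.DataFrame:
    """Intermediate (q75−q50) and maximum (q90−q50) potentials, Pg C.

    Raises if any zone shows crossing totals (upper percentile below the
    median), which the non-crossing enforcement upstream should preclude.
    """
    t = report.table
    if (t["q75_pg"] < t["q50_pg"] - 1e-9).any() or (t["q90_pg"] < t["q75_pg"] - 1e-9).any():
        raise ValueError("crossing quantile totals")
    out = pd.DataFrame(
        {
            "intermediate_pg": t["q75_pg"] - t["q50_pg"],
            "maximum_pg": t["q90_pg"] - t["q50_pg"],
        },
        index=t.index,
    )
    out.loc["Global"] = out.sum()
    return out


def zone_share(report: ZoneReport, zones, level: str = "q75"):
    """Share of the global additional potential held by a subset of zones.

    Returns (subset potential in Pg C, fraction of the global potential).
    """
    unknown = [z for z in zones if z not in report.table.index]
    if unknown:
        raise KeyError(f"unknown zones: {unknown}")
    pot = report.zone_potentials(level)
    subset = float(pot.loc[list(zones)].sum())
    total = report.potential(level)
    return subset, (subset / total if total else 0.0)
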