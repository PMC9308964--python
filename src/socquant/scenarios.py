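"""Sequestration scenarios: 4‰ timelines, historical carbon debt, climate shifts.

Three scenario families sit on top of the quantile predictions and stock
accounting:

* **4 per mille** — how long a linear accumulation of ``rate`` × baseline
  stock per year (default 0.004 yr⁻¹, the COP21 aspirational rate) takes to
  close the gap between the current (q50) stock and a higher percentile.
* **Historical carbon debt** — what croplands would hold had they stayed
  under natural cover, proxied by re-predicting the same cells with the land
  cover substituted (pasture/natural at q50, forest at q90); the mean of the
  resulting range is the headline debt.
* **Climate projection** — re-predicting with replaced temperature and
  precipitation layers and measuring the percent reduction of stocks and
  potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stocks import KG_M2_KM2_TO_PG, aggregate, stock_grid

FOUR_PER_MILLE = 0.004


def years_to_target(s0, st, rate: float = FOUR_PER_MILLE):
    """Years for a linear accumulation of rate·s0 per year to grow s0 → st.

    years = (st/s0 − 1)/rate. Cells with st < s0 (negative potential) are
    reported as 0 years; scalar inputs return (years, n_negative) with a
    float years.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    s0 = np.asarray(s0, dtype=float)
    st = np.asarray(st, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("baseline stock must be positive")
    years = (st / s0 - 1.0) / rate
    n_negative = int(np.sum(years < 0))
    years = np.maximum(years, 0.0)
    if years.ndim == 0:
        return float(years), n_negative
    return years, n_negative


def years_summary(years: np.ndarray, mask=None) -> dict:
    """Median and quartiles of a per-cell years map."""
    vals = np.asarray(years, dtype=float).ravel()
    if mask is not None:
        vals = vals[np.asarray(mask).ravel().astype(bool)]
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    return {"median_years": float(q50), "q25_years": float(q25),
            "q75_years": float(q75), "n_cells": int(vals.size)}


def average_capture_rate(total_added_pg: float, years: float,
                         reference_emissions_pg: float | None = None):
    """Mean annual capture (Pg C yr⁻¹) implied by adding ``total_added_pg``
    over ``years``; optionally also the share of a reference emission flux."""
    if years <= 0:
        raise ValueError("years must be positive")
    rate = total_added_pg / years
    if reference_emissions_pg is None:
        return rate
    return rate, rate / reference_emissions_pg


def bounded_debt_from_loss_fraction(current_pg: float, loss_low: float,
                                    loss_high: float):
    """Pre-agriculture stock and debt range implied by a fractional-loss premise.

    If cultivated soils hold ``loss`` less carbon than their natural
    counterparts, pre-agriculture stock = current/(1−loss) and the debt is
    the difference; evaluated at both bounds.
    """
    if not 0.0 < loss_low <= loss_high < 1.0:
        raise ValueError("loss fractions must satisfy 0 < low <= high < 1")
    pre = (current_pg / (1.0 - loss_low), current_pg / (1.0 - loss_high))
    debt = (pre[0] - current_pg, pre[1] - current_pg)
    return pre, debt


@dataclass
class DebtResult:
    debt_pasture_q50_pg: float
    debt_forest_q90_pg: float

    @property
    def range(self):
        lo = min(self.debt_pasture_q50_pg, self.debt_forest_q90_pg)
        hi = max(self.debt_pasture_q50_pg, self.debt_forest_q90_pg)
        return lo, hi

    @property
    def mean(self) -> float:
        lo, hi = self.range
        return 0.5 * (lo + hi)


def substitution_debt(model, grid, mask=None, clip_negative: bool = False,
                      depth_m: float = 0.3, fixed_bd=None) -> DebtResult:
    """Historical carbon debt of cropland cells by land-cover substitution.

    Re-predicts masked cells as (a) pasture/natural at the median and (b)
    forest at the 90th percentile, differences against the cropland median
    stock summed over cells (signed by default; ``clip_negative`` keeps only
    positive per-cell gaps). Requires a pooled model with the land-cover
    covariate.
    """
    import xarray as xr

    if getattr(model.standardizer, "landcover_col", None) is None:
        raise ValueError("substitution debt needs a pooled model with the "
                         "land-cover covariate")
    mask = (grid["cropland_mask"].values if mask is None
            else np.asarray(mask)).astype(bool)
    area = grid["area_km2"].values

    def total(ds_grid, var):
        stocks = stock_grid(model.predict_grid(ds_grid)[[var]], depth_m, fixed_bd=fixed_bd)
        return stocks[var].values

    current = total(grid, "q50")
    as_pasture = grid.copy()
    as_pasture["landcover"] = xr.zeros_like(grid["landcover"]) + 1
    as_forest = grid.copy()
    as_forest["landcover"] = xr.zeros_like(grid["landcover"]) + 2

    def debt(sub_stock):
        diff = sub_stock - current
        if clip_negative:
            diff = np.maximum(diff, 0.0)
        return float(np.sum(diff[mask] * area[mask]) * KG_M2_KM2_TO_PG)

    return DebtResult(
        debt_pasture_q50_pg=debt(total(as_pasture, "q50")),
        debt_forest_q90_pg=debt(total(as_forest, "q90")),
    )


@dataclass
class ClimateDelta:
    baseline_pg: dict
    projected_pg: dict
    percent_change: dict = field(init=False)

    def __post_init__(self):
        self.percent_change = {
            k: (0.0 if self.baseline_pg[k] == 0 else
                (self.baseline_pg[k] - self.projected_pg[k]) / self.baseline_pg[k] * 100.0)
            for k in self.baseline_pg
        }


def percent_reduction(baseline: float, projected: float) -> float:
    """(baseline − projected)/baseline × 100."""
    return (baseline - projected) / baseline * 100.0


def climate_projection(model, grid, mat_future, tap_future, mask=None,
                       depth_m: float = 0.3, fixed_bd=None) -> ClimateDelta:
    """Stocks and potentials under a replaced climate.

    ``mat_future``/``tap_future`` must match the grid geometry. Returns
    totals (q50 stock, q75/q90 potentials, all Pg C over masked cells) for
    both climates and their percent changes.
    """
    mat_future = np.asarray(mat_future, dtype=float)
    tap_future = np.asarray(tap_future, dtype=float)
    if mat_future.shape != grid["mat"].shape or tap_future.shape != grid["tap"].shape:
        raise ValueError("projected climate layers do not match the grid geometry")
    mask = grid["cropland_mask"].values if mask is None else np.asarray(mask)
    future = grid.copy(deep=True)
    future["mat"].values[:] = mat_future
    future["tap"].values[:] = tap_future

    def totals(g):
        stocks = stock_grid(model.predict_grid(g), depth_m, fixed_bd=fixed_bd)
        rep = aggregate(stocks, g["area_km2"].values,
                        np.zeros_like(g["mat"].values, dtype=int), mask=mask)
        g50 = float(rep.table["q50_pg"].sum())
        return {
            "stock_q50": g50,
            "potential_q75": float(rep.table["q75_pg"].sum()) - g50,
            "potential_q90": float(rep.table["q90_pg"].sum()) - g50,
        }

    return ClimateDelta(baseline_pg=totals(grid), projected_pg=totals(future))
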