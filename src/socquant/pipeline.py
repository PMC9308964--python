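"""End-to-end orchestration: synthesize → harmonize → fit → predict → account.

One :class:`RunConfig` (serializable to YAML) drives the whole chain with a
single seed; every stage writes its artifacts and parameters into an
append-only run directory, tagged with the config hash, so a run can be
reproduced or resumed stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scenarios, spline, stocks, synthetic
from .attribution import contribution_change, shapley_sample, to_long_csv
from .model import ModelSpec, TrainingConfig, rmse_q50, split_data, train
from .ptf import fit_ptf
from .synthetic import SyntheticConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 42
    run_dir: str = "run"
    n_sites: int = 5000
    layers_per_site: int = 4
    grid_nx: int = 32
    grid_ny: int = 32
    n_bd_pairs: int = 2000
    bd_noise_sd: float = 0.25
    spline_lambda: float = 0.1
    min_depth_cm: float = 20.0
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 0.003
    lr_final_fraction: float = 0.03
    test_fraction: float = 0.05
    accumulation_rate: float = 0.004
    mat_delta_c: float = 2.0
    tap_factor: float = 1.0
    n_attribution_instances: int = 20
    n_attribution_permutations: int = 100
    verbosity: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the summary dict.

    Artifacts land in ``config.run_dir``: site/profile/pair CSVs, the
    covariate grid and quantile predictions as NetCDF, the zone report CSV,
    attribution CSVs and ``summary.json``.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(config.to_yaml())
    seed = config.seed

    # --- synthesize -------------------------------------------------------
    syn = SyntheticConfig(n_sites=config.n_sites, seed=seed)
    sites = synthetic.generate_sites(syn)
    profiles_table = synthetic.generate_profiles(sites, config.layers_per_site, seed + 1)
    bd_pairs = synthetic.generate_bd_pairs(config.n_bd_pairs, config.bd_noise_sd, seed + 2)
    grid = synthetic.generate_grid(config.grid_nx, config.grid_ny, syn, seed + 3)
    sites.to_csv(run_dir / "sites.csv", index=False)
    profiles_table.to_csv(run_dir / "profiles.csv", index=False)
    bd_pairs.to_csv(run_dir / "bd_pairs.csv", index=False)
    grid.to_netcdf(run_dir / "grid.nc")

    # --- harmonize --------------------------------------------------------
    profiles = spline.profiles_from_table(profiles_table)
    harmonized, harm_report = spline.harmonize_dataset(
        profiles, config.spline_lambda, config.min_depth_cm
    )
    samples = harmonized.merge(
        sites[["site_id", "mat", "tap", "elevation", "landcover"]], on="site_id"
    ).rename(columns={"oc_pct_0_30": "soc_pct"})
    samples.to_csv(run_dir / "harmonized.csv", index=False)

    # --- pedotransfer -----------------------------------------------------
    ptf_fit = fit_ptf(bd_pairs["oc_gkg"], bd_pairs["bd_gcm3"], seed=seed + 4)
    (run_dir / "ptf.json").write_text(json.dumps({
        "a": ptf_fit.coeffs.a, "b": ptf_fit.coeffs.b, "c": ptf_fit.coeffs.c,
        "d": ptf_fit.coeffs.d, "rmse": ptf_fit.rmse, "bias": ptf_fit.bias,
    }, indent=2))

    # --- train ------------------------------------------------------------
    _, test_idx, resamples = split_data(samples, config.test_fraction, seed + 5)
    train_idx = resamples[0][0]
    training = TrainingConfig(
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        test_fraction=config.test_fraction, seed=seed + 6,
        lr_final_fraction=config.lr_final_fraction,
    )
    model = train(samples.iloc[train_idx], ModelSpec(), training)
    model.save(run_dir / "model")
    test_rmse = rmse_q50(model, samples.iloc[test_idx])

    # --- predict + account ------------------------------------------------
    quantiles = model.predict_grid(grid)
    quantiles.to_netcdf(run_dir / "quantiles.nc")
    stock_ds = stocks.stock_grid(quantiles[["q50", "q75", "q90"]], ptf=ptf_fit.coeffs)
    report = stocks.aggregate(
        stock_ds, grid["area_km2"].values, grid["zone"].values,
        mask=grid["cropland_mask"].values,
    )
    report.table.to_csv(run_dir / "zone_report.csv")
    potentials = stocks.additional_potential(report)

    # --- scenarios --------------------------------------------------------
    mask = grid["cropland_mask"].values
    s0 = stock_ds["q50"].values
    years75, _ = scenarios.years_to_target(s0, stock_ds["q75"].values,
                                           config.accumulation_rate)
    years90, _ = scenarios.years_to_target(s0, stock_ds["q90"].values,
                                           config.accumulation_rate)
    sum75 = scenarios.years_summary(years75, mask)
    sum90 = scenarios.years_summary(years90, mask)
    debt = scenarios.substitution_debt(model, grid, fixed_bd=None)
    delta = scenarios.climate_projection(
        model, grid,
        grid["mat"].values + config.mat_delta_c,
        grid["tap"].values * config.tap_factor,
    )

    # --- attribution ------------------------------------------------------
    rng = np.random.default_rng(seed + 7)
    inst_idx = rng.choice(len(samples), size=min(config.n_attribution_instances,
                                                 len(samples)), replace=False)
    bg_idx = rng.choice(len(samples), size=min(100, len(samples)), replace=False)
    attr = shapley_sample(model, samples.iloc[inst_idx], samples.iloc[bg_idx],
                          n_permutations=config.n_attribution_permutations,
                          seed=seed + 8)
    to_long_csv(attr, run_dir / "attributions.csv")
    change75 = contribution_change(attr, "q50", "q75")
    change90 = contribution_change(attr, "q50", "q90")

    g = report.global_total
    summary = {
        "config_hash": config.config_hash,
        "n_samples": int(len(samples)),
        "harmonization": harm_report,
        "ptf_rmse_gcm3": ptf_fit.rmse,
        "test_rmse_q50_pct": test_rmse,
        "global_stock_pg": {"q50": float(g["q50_pg"]), "q75": float(g["q75_pg"]),
                            "q90": float(g["q90_pg"])},
        "additional_potential_pg": {
            "intermediate": float(potentials.loc["Global", "intermediate_pg"]),
            "maximum": float(potentials.loc["Global", "maximum_pg"]),
        },
        "years_to_q75": sum75,
        "years_to_q90": sum90,
        "debt_range_pg": list(debt.range),
        "debt_mean_pg": debt.mean,
        "climate_percent_change": delta.percent_change,
        "contribution_change_pct": {
            "to_q75": {k: float(v) for k, v in change75.items()},
            "to_q90": {k: float(v) for k, v in change90.items()},
        },
    }
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


# ---------------------------------------------------------------------------
# published-table arithmetic
# ---------------------------------------------------------------------------

#: constants of the published accounting narrative, used as *inputs* when
#: re-deriving its arithmetic: the printed median years-to-target of the 4‰
#: map, the emission flux the 4‰ rate was derived from, the external 62 Pg
#: cropland stock estimate with its 25–75 % loss premise, the 10–160 Pg
#: substitution-debt range, and the two debt midpoints used in different
#: sections (85 and 92 Pg).
PUBLISHED = {
    "median_years_q75": 86.0,
    "median_years_q90": 200.0,
    "reference_emissions_pg_yr": 8.9,
    "external_cropland_stock_pg": 62.0,
    "loss_fraction_low": 0.25,
    "loss_fraction_high": 0.75,
    "model_debt_range_pg": (10.0, 160.0),
    "debt_midpoint_body_pg": 85.0,
    "debt_midpoint_conclusions_pg": 92.0,
    "share_ecoregions": ("Temperate broadleaf and mixed forests",
                         "Temperate grasslands, savannas and shrublands"),
}


def report_table1_arithmetic() -> dict:
    """Recompute every accounting quantity derivable from the packaged
    ecoregion table and the published premises; returns a flat dict of
    computed values (Pg C, years, percent)."""
    report = stocks.load_table1()
    g = report.global_total
    pot75 = report.potential("q75")
    pot90 = report.potential("q90")
    subset75, share75 = stocks.zone_share(report, PUBLISHED["share_ecoregions"], "q75")
    subset90, share90 = stocks.zone_share(report, PUBLISHED["share_ecoregions"], "q90")
    rate75, emis_share = scenarios.average_capture_rate(
        pot75, PUBLISHED["median_years_q75"], PUBLISHED["reference_emissions_pg_yr"])
    pre, debt = scenarios.bounded_debt_from_loss_fraction(
        PUBLISHED["external_cropland_stock_pg"],
        PUBLISHED["loss_fraction_low"], PUBLISHED["loss_fraction_high"])
    lo, hi = PUBLISHED["model_debt_range_pg"]
    midpoint = 0.5 * (lo + hi)
    return {
        "global_stock_q50_pg": float(g["q50_pg"]),
        "global_stock_q75_pg": float(g["q75_pg"]),
        "global_stock_q90_pg": float(g["q90_pg"]),
        "global_area_km2": float(g["area_km2"]),
        "potential_intermediate_pg": pot75,
        "potential_maximum_pg": pot90,
        "two_ecoregion_potential_q75_pg": subset75,
        "two_ecoregion_share_q75_pct": share75 * 100.0,
        "two_ecoregion_share_q90_pct": share90 * 100.0,
        "capture_rate_q75_pg_yr": rate75,
        "capture_rate_q90_pg_yr": scenarios.average_capture_rate(
            pot90, PUBLISHED["median_years_q90"]),
        "capture_emission_share_pct": emis_share * 100.0,
        "preagriculture_low_pg": pre[0],
        "preagriculture_high_pg": pre[1],
        "debt_premise_low_pg": debt[0],
        "debt_premise_high_pg": debt[1],
        "model_debt_midpoint_pg": midpoint,
        "recoup_q75_of_midpoint_pct": pot75 / midpoint * 100.0,
        "recoup_q90_of_midpoint_pct": pot90 / midpoint * 100.0,
        "recoup_q75_of_92_pct": pot75 / PUBLISHED["debt_midpoint_conclusions_pg"] * 100.0,
        "recoup_q90_of_92_pct": pot90 / PUBLISHED["debt_midpoint_conclusions_pg"] * 100.0,
    }


def verification_table() -> pd.DataFrame:
    """Computed accounting quantities side by side with the published
    rounded figures they should reproduce."""
    computed = report_table1_arithmetic()
    printed = {
        "global_stock_q50_pg": 82.68,
        "potential_intermediate_pg": 29.0,
        "potential_maximum_pg": 65.0,
        "two_ecoregion_potential_q75_pg": 17.2,
        "two_ecoregion_share_q75_pct": 59.0,
        "capture_rate_q75_pg_yr": 0.34,
        "capture_emission_share_pct": 4.0,
        "preagriculture_high_pg": 248.0,
        "debt_premise_low_pg": 21.0,
        "debt_premise_high_pg": 186.0,
        "model_debt_midpoint_pg": 85.0,
        "recoup_q75_of_92_pct": 32.0,
        "recoup_q90_of_92_pct": 72.0,
    }
    rows = [
        {"quantity": k, "computed": round(computed[k], 3),
         "published": printed.get(k)}
        for k in computed
    ]
    return pd.DataFrame(rows).set_index("quantity")
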