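"""Synthetic soil-carbon data with analytically known conditional quantiles.

Real global SOC compilations (WoSIS-style profile collections joined to
climate, terrain and land-cover layers) cannot ship with a test suite, so this
module generates stand-ins whose statistical structure matches what the
downstream stages assume: layered profiles with depth-decaying carbon, three
modelled land-cover groups, and a right-skewed SOC distribution conditional on
climate. The conditional law is lognormal, which makes every conditional
quantile available in closed form via :func:`true_quantile` — the oracle that
model-recovery and coverage tests are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

LANDCOVER_CLASSES = ("cropland", "pasture_natural", "forest")

#: additive land-cover offsets on the log-SOC location; pasture/natural and
#: forest sit above cropland so their upper quantiles dominate at equal climate
DEFAULT_LANDCOVER_OFFSETS = {
    "cropland": 0.0,
    "pasture_natural": 0.28,
    "forest": 0.40,
}

#: per-covariate slopes of the log-SOC location on standardized covariates;
#: SOC falls with temperature and rises with rainfall and elevation
DEFAULT_EFFECT_WEIGHTS = {"mat": -0.40, "tap": 0.35, "elevation": 0.12}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic site generator.

    ``sigma_log`` is the dispersion of log-SOC; 0.5 gives the strongly
    right-skewed conditional distribution seen in field SOC data (q90/q50
    around 1.9). ``landcover_sigma_log`` optionally widens the dispersion per
    class, which makes the land-cover influence grow toward upper percentiles.
    """

    n_sites: int = 5000
    seed: int = 42
    mat_range: tuple[float, float] = (-10.0, 30.0)
    tap_range: tuple[float, float] = (50.0, 3000.0)
    elev_range: tuple[float, float] = (0.0, 3000.0)
    landcover_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    sigma_log: float = 0.5
    mu_intercept: float = 0.40  # log(%) at mid-range climate under cropland
    effect_weights: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS))
    landcover_offsets: dict = field(
        default_factory=lambda: dict(DEFAULT_LANDCOVER_OFFSETS)
    )
    landcover_sigma_log: dict | None = None
    year_range: tuple[int, int] = (1980, 2017)

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be positive")
        if abs(sum(self.landcover_probs) - 1.0) > 1e-9:
            raise ValueError("landcover_probs must sum to 1")
        for name, rng in (
            ("mat_range", self.mat_range),
            ("tap_range", self.tap_range),
            ("elev_range", self.elev_range),
        ):
            if not rng[1] > rng[0]:
                raise ValueError(f"{name} must be a non-degenerate interval")

    def standardize(self, name: str, values: np.ndarray) -> np.ndarray:
        """Map a covariate onto roughly [-1, 1] using its configured range."""
        lo, hi = getattr(self, f"{name[:4] if name == 'elevation' else name}_range")
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        return (np.asarray(values, dtype=float) - mid) / half

    def sigma_for(self, landcover: np.ndarray) -> np.ndarray:
        if self.landcover_sigma_log is None:
            return np.full(len(landcover), self.sigma_log)
        return np.array(
            [self.landcover_sigma_log.get(lc, self.sigma_log) for lc in landcover]
        )


def _mu(config: SyntheticConfig, mat, tap, elevation, landcover) -> np.ndarray:
    """Location of log-SOC: linear in standardized covariates + class offset."""
    w = config.effect_weights
    mu = (
        config.mu_intercept
        + w["mat"] * config.standardize("mat", mat)
        + w["tap"] * config.standardize("tap", tap)
        + w["elevation"] * config.standardize("elevation", elevation)
    )
    offsets = np.array([config.landcover_offsets[lc] for lc in np.atleast_1d(landcover)])
    return mu + offsets


def generate_sites(config: SyntheticConfig) -> pd.DataFrame:
    """Draw site records with lognormal SOC conditional on climate and cover.

    Returns a frame with columns site_id, lon, lat, mat, tap, elevation,
    landcover, soc_pct, year. Deterministic for a fixed config (the seed is
    part of the config).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    mat = rng.uniform(*config.mat_range, n)
    tap = rng.uniform(*config.tap_range, n)
    elevation = rng.uniform(*config.elev_range, n)
    landcover = rng.choice(LANDCOVER_CLASSES, size=n, p=config.landcover_probs)
    mu = _mu(config, mat, tap, elevation, landcover)
    sigma = config.sigma_for(landcover)
    soc = np.exp(mu + sigma * rng.standard_normal(n))
    return pd.DataFrame(
        {
            "site_id": np.arange(n),
            "lon": rng.uniform(-180, 180, n).round(5),
            "lat": rng.uniform(-60, 80, n).round(5),
            "mat": mat,
            "tap": tap,
            "elevation": elevation,
            "landcover": landcover,
            "soc_pct": soc,
            "year": rng.integers(config.year_range[0], config.year_range[1] + 1, n),
        }
    )


def true_quantile(
    config: SyntheticConfig,
    tau: float,
    mat,
    tap,
    elevation,
    landcover,
) -> np.ndarray:
    """Closed-form conditional SOC quantile under the generating lognormal law.

    ``q_tau(x) = exp(mu(x) + sigma * z_tau)`` with ``z_tau`` the standard
    normal quantile. This is the analytic oracle the trained quantile network
    is compared against.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly inside (0, 1)")
    mu = _mu(config, mat, tap, elevation, landcover)
    sigma = config.sigma_for(np.atleast_1d(landcover))
    q = np.exp(mu + sigma * stats.norm.ppf(tau))
    if np.ndim(mat) == 0 and isinstance(landcover, str):
        return float(q[0])
    return q


def true_quantile_frame(config: SyntheticConfig, sites: pd.DataFrame, tau: float):
    """Vectorized :func:`true_quantile` over a site table."""
    return true_quantile(
        config,
        tau,
        sites["mat"].to_numpy(),
        sites["tap"].to_numpy(),
        sites["elevation"].to_numpy(),
        sites["landcover"].to_numpy(),
    )


def generate_profiles(
    sites: pd.DataFrame, layers_per_site: int, seed: int
) -> pd.DataFrame:
    """Expand 0–30 cm site values into layered profiles over 0–100 cm.

    Layer values follow an exponential depth decay ``f(d) = A exp(-k d)``
    whose 0–30 cm mean is scaled to equal the site's ``soc_pct`` exactly; a
    layer boundary is always placed at 30 cm so the depth-weighted 0–30 cm
    mean of the discrete layers reproduces the stored truth to machine
    precision. Returns a long table (site_id, top_cm, bottom_cm, oc_pct).
    """
    if layers_per_site < 1:
        raise ValueError("layers_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for site_id, soc in zip(sites["site_id"].to_numpy(), sites["soc_pct"].to_numpy()):
        k = rng.uniform(0.01, 0.035)
        # scale so the mean of A exp(-k d) over [0, 30] equals soc
        amp = soc * 30.0 * k / (1.0 - np.exp(-30.0 * k))
        if layers_per_site == 1:
            breaks = np.array([0.0, 30.0])
        else:
            n_top = max(1, round(layers_per_site * 0.4))
            n_top = min(n_top, layers_per_site - 1)
            n_bot = layers_per_site - n_top
            top_breaks = np.sort(rng.uniform(2.0, 28.0, n_top - 1)) if n_top > 1 else []
            bot_breaks = np.sort(rng.uniform(32.0, 98.0, n_bot - 1)) if n_bot > 1 else []
            breaks = np.concatenate([[0.0], top_breaks, [30.0], bot_breaks, [100.0]])
        for top, bottom in zip(breaks[:-1], breaks[1:]):
            mean_val = amp * (np.exp(-k * top) - np.exp(-k * bottom)) / (
                k * (bottom - top)
            )
            rows.append((site_id, top, bottom, mean_val))
    return pd.DataFrame(rows, columns=["site_id", "top_cm", "bottom_cm", "oc_pct"])


def generate_bd_pairs(
    n: int, noise_sd: float, seed: int, coeffs=None
) -> pd.DataFrame:
    """(oc g kg⁻¹, bulk density g cm⁻³) pairs scattered around the rational PTF.

    The oc values span 0–150 g kg⁻¹ (forced endpoints) so the rational-function
    fit is identifiable; noise is Gaussian with sd ``noise_sd`` truncated below
    at 0.05 g cm⁻³.
    """
    from .ptf import GLOBAL_PTF, evaluate_ptf

    if n < 10:
        raise ValueError("need at least 10 pairs")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    coeffs = coeffs or GLOBAL_PTF
    rng = np.random.default_rng(seed)
    oc = rng.uniform(0.0, 160.0, n)
    oc[0], oc[1] = 0.0, 150.0
    bd = evaluate_ptf(oc, coeffs) + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({"oc_gkg": oc, "bd_gcm3": np.maximum(bd, 0.05)})


def _smooth_field(rng: np.random.Generator, nx: int, ny: int) -> np.ndarray:
    """Low-frequency random surface in [0, 1] via coarse noise + spline zoom."""
    coarse_ny, coarse_nx = max(2, ny // 8 + 2), max(2, nx // 8 + 2)
    coarse = rng.standard_normal((coarse_ny, coarse_nx))
    f = ndimage.zoom(coarse, (ny / coarse_ny, nx / coarse_nx), order=3, mode="nearest")
    f = f[:ny, :nx]
    if f.shape != (ny, nx):  # zoom can undershoot by one cell
        out = np.empty((ny, nx))
        out[: f.shape[0], : f.shape[1]] = f
        out[f.shape[0]:, :] = f[-1:, : nx] if f.shape[1] >= nx else 0.0
        out[:, f.shape[1]:] = out[:, f.shape[1] - 1 : f.shape[1]]
        f = out
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.full((ny, nx), 0.5)


def generate_grid(nx: int, ny: int, config: SyntheticConfig, seed: int, n_zones: int = 4):
    """Covariate raster stack as an xarray Dataset.

    Variables: ``mat`` (°C), ``tap`` (mm), ``elevation`` (m) as smooth random
    surfaces within the configured ranges; ``landcover`` (class codes with the
    configured class frequencies); ``zone`` (n_zones contiguous-ish strata);
    ``area_km2`` per cell (0.25 km², the 500 m grid); ``cropland_mask``.
    """
    import xarray as xr

    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    coords = {"y": np.arange(ny), "x": np.arange(nx)}

    def scaled(name):
        lo, hi = getattr(config, f"{name}_range")
        return lo + (hi - lo) * _smooth_field(rng, nx, ny)

    mat, tap, elev = scaled("mat"), scaled("tap"), scaled("elev")
    lc_field = _smooth_field(rng, nx, ny) + 0.05 * rng.standard_normal((ny, nx))
    probs = np.asarray(config.landcover_probs)
    edges = np.quantile(lc_field, np.cumsum(probs)[:-1])
    landcover = np.digitize(lc_field, edges)  # 0=cropland, 1=pasture_natural, 2=forest
    zone_field = _smooth_field(rng, nx, ny)
    zone_edges = np.quantile(zone_field, np.linspace(0, 1, n_zones + 1)[1:-1])
    zone = np.digitize(zone_field, zone_edges) if n_zones > 1 else np.zeros((ny, nx), int)
    # int32 / int8 rather than int64 / bool keeps the stack writable as
    # plain NetCDF3 through the scipy engine
    ds = xr.Dataset(
        {
            "mat": (("y", "x"), mat),
            "tap": (("y", "x"), tap),
            "elevation": (("y", "x"), elev),
            "landcover": (("y", "x"), landcover.astype(np.int32)),
            "zone": (("y", "x"), np.asarray(zone, dtype=np.int32)),
            "area_km2": (("y", "x"), np.full((ny, nx), 0.25)),
            "cropland_mask": (("y", "x"), (landcover == 0).astype(np.int8)),
        },
        coords=coords,
        attrs={"landcover_classes": ",".join(LANDCOVER_CLASSES)},
    )
    return ds


def write_sites_csv(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, index=False)


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=seed)
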