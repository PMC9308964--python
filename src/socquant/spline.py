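"""Depth harmonization of layered soil profiles with the equal-area spline.

Legacy soil profiles report carbon over heterogeneous depth intervals; digital
soil mapping needs one value per site over a fixed support (0–30 cm here).
The standard tool is the equal-area smoothing spline: a continuous,
continuously-differentiable piecewise-quadratic function f(d) minimizing

    (1/n) * sum_i (mean of f over layer i - y_i)^2 + lambda * ∫ f'(d)^2 dd

so the fitted curve's layer averages honor the measured layer values
("equal area") while the roughness penalty keeps it smooth. The minimizer
over all square-integrable-derivative functions is itself piecewise quadratic
on the layer partition, so the problem is solved exactly as a small
equality-constrained quadratic program (KKT linear system).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SoilProfile:
    """One site's layered measurements: (top, bottom, value) in cm and % mass."""

    site_id: object
    layers: tuple  # of (top_cm, bottom_cm, value)

    def __post_init__(self):
        layers = tuple(tuple(map(float, l[:2])) + (float(l[2]),) for l in self.layers)
        object.__setattr__(self, "layers", layers)
        if not layers:
            raise ValueError("profile has no layers")
        prev_bottom = -np.inf
        for top, bottom, _ in layers:
            if not 0 <= top < bottom:
                raise ValueError(f"invalid layer interval ({top}, {bottom})")
            if top < prev_bottom:
                raise ValueError("layers overlap or are unsorted")
            prev_bottom = bottom

    @property
    def max_depth(self) -> float:
        return self.layers[-1][1]


@dataclass
class SplineFit:
    """Piecewise-quadratic fit: on piece j, f(d) = a_j + b_j u + c_j u², u = d − knots[j]."""

    knots: np.ndarray          # piece boundaries, len m+1
    coeffs: np.ndarray         # (m, 3) rows of (a, b, c)
    lam: float
    extrapolation: tuple = field(default=(None, None))  # (above-top, below-bottom) values

    def __call__(self, depth) -> np.ndarray:
        d = np.asarray(depth, dtype=float)
        lo, hi = self.knots[0], self.knots[-1]
        j = np.clip(np.searchsorted(self.knots, d, side="right") - 1, 0, len(self.coeffs) - 1)
        u = d - self.knots[j]
        a, b, c = self.coeffs[j, 0], self.coeffs[j, 1], self.coeffs[j, 2]
        out = a + b * u + c * u * u
        above, below = self.extrapolation
        if above is not None:
            out = np.where(d < lo, above, out)
        if below is not None:
            out = np.where(d > hi, below, out)
        return out

    def piece_integral(self, j: int, lo: float, hi: float) -> float:
        """∫ f over [lo, hi] within piece j (absolute depths)."""
        a, b, c = self.coeffs[j]
        t = self.knots[j]
        F = lambda d: a * (d - t) + b * (d - t) ** 2 / 2 + c * (d - t) ** 3 / 3
        return F(hi) - F(lo)


def _build_pieces(profile: SoilProfile):
    """Piece boundaries = union of layer edges; map each measured layer to its piece."""
    edges = sorted({e for top, bottom, _ in profile.layers for e in (top, bottom)})
    knots = np.asarray(edges, dtype=float)
    layer_piece, values = [], []
    for top, bottom, value in profile.layers:
        j = int(np.searchsorted(knots, top))
        layer_piece.append(j)
        values.append(value)
    return knots, layer_piece, np.asarray(values)


def fit_equal_area_spline(profile: SoilProfile, lam: float = 0.1) -> SplineFit:
    """Fit the equal-area smoothing spline to one profile.

    Parameters
    ----------
    profile : SoilProfile
    lam : float
        Roughness weight λ ≥ 0. As λ → 0 the layer means of the fit converge
        to the observed values; large λ flattens the curve toward the grand
        mean. 0.1 is the conventional default.

    Notes
    -----
    Unknowns are the 3 coefficients per piece; continuity of value and first
    derivative at interior knots are equality constraints; the data +
    roughness objective is quadratic, so the KKT system is linear and solved
    directly. A vanishing Tikhonov term on the roughness selects the smoothest
    minimizer when λ = 0 (otherwise constants in the null space are free).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    knots, layer_piece, y = _build_pieces(profile)
    m = len(knots) - 1
    n = len(y)
    h = np.diff(knots)

    if n == 1 and m == 1:
        fit = SplineFit(knots, np.array([[y[0], 0.0, 0.0]]), lam)
        _attach_extrapolation(fit, profile)
        return fit

    # data term: layer mean of piece j is a + b h/2 + c h^2/3
    M = np.zeros((n, 3 * m))
    for row, j in enumerate(layer_piece):
        M[row, 3 * j : 3 * j + 3] = [1.0, h[j] / 2.0, h[j] ** 2 / 3.0]

    # roughness: ∫ (b + 2cu)^2 du over each piece
    R = np.zeros((3 * m, 3 * m))
    for j in range(m):
        hj = h[j]
        R[3 * j + 1, 3 * j + 1] += hj
        R[3 * j + 1, 3 * j + 2] += hj ** 2
        R[3 * j + 2, 3 * j + 1] += hj ** 2
        R[3 * j + 2, 3 * j + 2] += 4.0 * hj ** 3 / 3.0

    H = 2.0 * (M.T @ M / n + lam * R + 1e-12 * R)
    g = -2.0 * (M.T @ y) / n

    # continuity constraints at interior knots
    A = np.zeros((2 * (m - 1), 3 * m))
    for j in range(m - 1):
        hj = h[j]
        A[2 * j, 3 * j : 3 * j + 3] = [1.0, hj, hj ** 2]
        A[2 * j, 3 * (j + 1)] = -1.0
        A[2 * j + 1, 3 * j + 1 : 3 * j + 3] = [1.0, 2.0 * hj]
        A[2 * j + 1, 3 * (j + 1) + 1] = -1.0

    k = A.shape[0]
    kkt = np.block([[H, A.T], [A, np.zeros((k, k))]])
    rhs = np.concatenate([-g, np.zeros(k)])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    coeffs = sol[: 3 * m].reshape(m, 3)
    fit = SplineFit(knots, coeffs, lam)
    _attach_extrapolation(fit, profile)
    return fit


def _attach_extrapolation(fit: SplineFit, profile: SoilProfile) -> None:
    """Constant extension beyond the measured support, anchored at the
    midpoints of the shallowest and deepest layers."""
    top0, bottom0, _ = profile.layers[0]
    topn, bottomn, _ = profile.layers[-1]
    fit.extrapolation = (
        float(fit(0.5 * (top0 + bottom0))),
        float(fit(0.5 * (topn + bottomn))),
    )


def depth_average(fit: SplineFit, top: float, bottom: float) -> float:
    """Mean of the fitted function over [top, bottom] cm.

    Depths outside the fitted support use the constant extrapolation values
    attached to the fit.
    """
    if not top < bottom:
        raise ValueError("need top < bottom")
    lo, hi = fit.knots[0], fit.knots[-1]
    total = 0.0
    above, below = fit.extrapolation
    if top < lo:
        total += (min(bottom, lo) - top) * (above if above is not None else fit.coeffs[0, 0])
    if bottom > hi:
        total += (bottom - max(top, hi)) * (
            below if below is not None else float(fit(hi))
        )
    a, b = max(top, lo), min(bottom, hi)
    if a < b:
        j_lo = int(np.clip(np.searchsorted(fit.knots, a, side="right") - 1, 0, len(fit.coeffs) - 1))
        j_hi = int(np.clip(np.searchsorted(fit.knots, b, side="left") - 1, 0, len(fit.coeffs) - 1))
        for j in range(j_lo, j_hi + 1):
            seg_lo = max(a, fit.knots[j])
            seg_hi = min(b, fit.knots[j + 1])
            if seg_hi > seg_lo:
                total += fit.piece_integral(j, seg_lo, seg_hi)
    return total / (bottom - top)


def profiles_from_table(table: pd.DataFrame, value_col: str = "oc_pct"):
    """Group a long layer table (site_id, top_cm, bottom_cm, value) into profiles."""
    out = []
    for site_id, grp in table.groupby("site_id", sort=True):
        grp = grp.sort_values("top_cm")
        out.append(
            SoilProfile(
                site_id,
                tuple(zip(grp["top_cm"], grp["bottom_cm"], grp[value_col])),
            )
        )
    return out


def harmonize_dataset(
    profiles,
    lam: float = 0.1,
    min_depth: float = 20.0,
    top: float = 0.0,
    bottom: float = 30.0,
) -> tuple[pd.DataFrame, dict]:
    """Standardize profiles to a single [top, bottom] cm value.

    Profiles whose measured support does not reach ``min_depth`` are dropped
    (too shallow to say anything about 0–30 cm); profiles reaching min_depth
    but not ``bottom`` are extended as constant from the deepest layer
    midpoint. Returns (table with site_id + harmonized value, report dict).
    """
    rows, dropped = [], 0
    for profile in profiles:
        if profile.max_depth < min_depth:
            dropped += 1
            continue
        fit = fit_equal_area_spline(profile, lam)
        rows.append((profile.site_id, depth_average(fit, top, bottom)))
    report = {"retained": len(rows), "dropped": dropped, "lambda": lam,
              "min_depth": min_depth}
    logger.info(
        "harmonized %d profiles (%d dropped below %.0f cm support)",
        report["retained"], dropped, min_depth,
    )
    return pd.DataFrame(rows, columns=["site_id", "oc_pct_0_30"]), report
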