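"""Bulk-density pedotransfer function (PTF).

Converting a carbon concentration to an areal stock needs the soil's bulk
density, which legacy profiles often lack. The PTF used here is the rational
function

    BD(oc) = (a − b·oc) / (c·oc + d)       [oc in g kg⁻¹, BD in g cm⁻³]

which decreases monotonically with carbon content (organic matter is light
and porous). The published global coefficients are the package default;
:func:`fit_ptf` refits the same form to any (oc, BD) sample.

The form is over-parametrized — scaling all four coefficients by k > 0 leaves
the curve unchanged — so fitting fixes d = 1 and the returned coefficients
are that normalized representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class PTFCoefficients:
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if self.d <= 0 or self.c < 0:
            raise ValueError("need c >= 0 and d > 0 for a positive denominator")
        if self.a / self.d <= 0:
            raise ValueError("BD at oc=0 must be positive")

    def normalized(self) -> "PTFCoefficients":
        """The d = 1 representative of the scale-equivalence class."""
        return PTFCoefficients(self.a / self.d, self.b / self.d, self.c / self.d, 1.0)


#: published global coefficients (oc in g kg⁻¹)
GLOBAL_PTF = PTFCoefficients(a=83.2687, b=0.011, c=0.635, d=52.847)


def evaluate_ptf(oc_gkg, coeffs: PTFCoefficients = GLOBAL_PTF) -> np.ndarray:
    """Bulk density (g cm⁻³) at carbon content ``oc_gkg`` (g kg⁻¹)."""
    oc = np.asarray(oc_gkg, dtype=float)
    if np.any(oc < 0):
        raise ValueError("oc must be non-negative")
    return (coeffs.a - coeffs.b * oc) / (coeffs.c * oc + coeffs.d)


def oc_pct_to_gkg(oc_pct) -> np.ndarray:
    """% mass → g kg⁻¹ (×10); the PTF's native unit is g kg⁻¹."""
    return 10.0 * np.asarray(oc_pct, dtype=float)


@dataclass
class PTFFitResult:
    coeffs: PTFCoefficients
    rmse: float
    bias: float
    n: int
    converged: bool
    n_iterations: int


def fit_ptf(oc_gkg, bd_gcm3, seed: int = 0, max_restarts: int = 5) -> PTFFitResult:
    """Nonlinear least-squares refit of the rational PTF.

    Optimizes BD = (a′ − b′·oc)/(c′·oc + 1) (d fixed at 1 for
    identifiability) from the data; restarts from seeded jitters of the
    initial point if the optimizer fails to converge.
    """
    oc = np.asarray(oc_gkg, dtype=float)
    bd = np.asarray(bd_gcm3, dtype=float)
    if len(oc) < 10:
        raise ValueError("need at least 10 pairs")
    if np.ptp(oc) <= 0:
        raise ValueError("degenerate input: all oc values equal")

    def residuals(theta):
        a, b, c = theta
        return (a - b * oc) / (np.maximum(c, 0.0) * oc + 1.0) - bd

    x0 = np.array([float(bd[np.argmin(oc)]), 0.0, 0.01])
    rng = np.random.default_rng(seed)
    last_exc = None
    for restart in range(max_restarts + 1):
        start = x0 if restart == 0 else x0 * (1 + 0.3 * rng.standard_normal(3))
        try:
            res = least_squares(residuals, start, method="lm", max_nfev=5000)
        except Exception as exc:  # singular Jacobian etc.
            last_exc = exc
            continue
        if res.success:
            a, b, c = res.x
            r = residuals(res.x)
            return PTFFitResult(
                coeffs=PTFCoefficients(a, b, max(c, 0.0), 1.0),
                rmse=float(np.sqrt(np.mean(r**2))),
                bias=float(np.mean(r)),
                n=len(oc),
                converged=True,
                n_iterations=int(res.nfev),
            )
    raise RuntimeError(f"PTF fit did not converge after {max_restarts} restarts: {last_exc}")
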