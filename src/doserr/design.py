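"""Design-stage diagnostics under dose uncertainty.

Before investing in a full Monte-Carlo dosimetry system it is worth asking
how much shared error would actually cost: these routines compute the
noncentrality parameter (NCP = beta^2 / Var(beta_hat)), power, and confidence
interval length for a Gaussian dose-response study under three nested
scenarios --

* ``none``     : X = Z, no dosimetry error; Var(beta_hat) from s^2 (Z'Z)^-1
* ``unshared`` : Berkson error with the off-diagonal of Var(X|W) zeroed
* ``shared``   : the full Var(X|W)

Effect sizes are expressed in units of the residual standard deviation sigma
(beta/sigma), since only that ratio matters for power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correction import (
    expected_ols_variance,
    gaussian_corrected_covariance,
    slope_variance_inflation,
    wald_ci,
)
from .realizations import DoseUncertaintyModel, decompose_sigma_k

__all__ = [
    "PowerCurve",
    "ncp",
    "power_from_ncp",
    "slope_variance",
    "power_curve",
    "ci_length_curve",
    "calibrate_slope_for_inflation",
]

SCENARIOS = ("none", "unshared", "shared")


@dataclass
class PowerCurve:
    effect_grid: np.ndarray          # beta / sigma
    ncp: dict[str, np.ndarray]       # per scenario
    power: dict[str, np.ndarray]     # per scenario, at alpha
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        cols = {"beta_over_sigma": self.effect_grid}
        for s in SCENARIOS:
            cols[f"ncp_{s}"] = self.ncp[s]
        for s in SCENARIOS:
            cols[f"power_{s}"] = self.power[s]
        return pd.DataFrame(cols)


def ncp(beta: float, var_beta: float) -> float:
    """Noncentrality parameter beta^2 / Var(beta_hat) of the slope test."""
    if var_beta <= 0:
        raise ValueError("Var(beta_hat) must be positive")
    return float(beta**2 / var_beta)


def power_from_ncp(ncp_value: float | np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """P(chi^2_1(ncp) > chi^2_1 upper-alpha quantile): two-sided slope test."""
    crit = stats.chi2.ppf(1 - alpha, df=1)
    return stats.ncx2.sf(crit, df=1, nc=np.maximum(np.asarray(ncp_value, float), 1e-300))


def slope_variance(
    z: np.ndarray,
    cov_xw: np.ndarray,
    sigma: float,
    beta: float,
    scenario: str,
) -> float:
    """Var(beta_hat) for one scenario: the (2,2) element of the corrected
    Gaussian covariance (full, diagonal-only, or error-free Var(X|W))."""
    z = np.asarray(z, dtype=float).ravel()
    zd = np.column_stack([np.ones_like(z), z])
    if scenario == "none":
        v = np.zeros_like(cov_xw)
    elif scenario == "unshared":
        v = np.diag(np.diag(cov_xw))
    elif scenario == "shared":
        v = cov_xw
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    cov = gaussian_corrected_covariance(zd, sigma**2, beta, v)
    return float(cov[1, 1])


def power_curve(
    z: np.ndarray,
    v: DoseUncertaintyModel,
    sigma: float,
    grid: np.ndarray | None = None,
    alpha: float = 0.05,
) -> PowerCurve:
    """NCP and power across effect sizes beta/sigma for the three scenarios.

    At beta = 0 power equals alpha exactly in every scenario.
    """
    z = np.asarray(z, dtype=float).ravel()
    if np.ptp(z) == 0:
        raise ValueError("constant dose vector")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 50)
    grid = np.asarray(grid, dtype=float)
    ncps: dict[str, np.ndarray] = {}
    powers: dict[str, np.ndarray] = {}
    for scen in SCENARIOS:
        vals = np.empty_like(grid)
        for i, g in enumerate(grid):
            beta = g * sigma
            var_b = slope_variance(z, v.covariance, sigma, beta, scen)
            vals[i] = beta**2 / var_b
        ncps[scen] = vals
        powers[scen] = np.where(grid == 0.0, alpha, power_from_ncp(vals, alpha))
    return PowerCurve(effect_grid=grid, ncp=ncps, power=powers, alpha=alpha)


def ci_length_curve(
    z: np.ndarray,
    v: DoseUncertaintyModel,
    sigma: float,
    grid: np.ndarray | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Naive / inhomogeneous-only / shared CI bounds across effect sizes.

    * naive: slope variance from the expected OLS estimate (what an analysis
      ignoring dose error would report, on average);
    * unshared: corrected variance with the off-diagonal of K zeroed
      (inhomogeneous Berkson error, no sharing);
    * shared: fully corrected variance.

    Widths are ordered naive <= unshared <= shared whenever within-group
    doses co-move (PSD increments), and all coincide at beta = 0.
    """
    z = np.asarray(z, dtype=float).ravel()
    if np.ptp(z) == 0:
        raise ValueError("constant dose vector")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 50)
    grid = np.asarray(grid, dtype=float)
    sigma2_xw, k = decompose_sigma_k(v.covariance)
    rows = []
    for g in grid:
        beta = g * sigma
        var_naive = float(
            expected_ols_variance(z, sigma**2, beta, sigma2_xw, k)[1, 1]
        )
        var_unshared = slope_variance(z, v.covariance, sigma, beta, "unshared")
        var_shared = slope_variance(z, v.covariance, sigma, beta, "shared")
        row = {"beta_over_sigma": g}
        for name, var in (
            ("naive", var_naive),
            ("unshared", var_unshared),
            ("shared", var_shared),
        ):
            lo, hi = wald_ci(beta, var, level)
            row[f"lower_{name}"], row[f"upper_{name}"] = lo / sigma, hi / sigma
            row[f"width_{name}"] = (hi - lo) / sigma
        rows.append(row)
    return pd.DataFrame(rows)


def calibrate_slope_for_inflation(
    z: np.ndarray,
    v: DoseUncertaintyModel,
    sigma: float,
    ratio: float = 1.0,
) -> float:
    """Slope beta at which the shared-error slope-variance inflation equals
    ``ratio`` times the error-free OLS slope variance s^2/(Z*'Z*).

    The inflation is proportional to beta^2, so the calibration is a single
    square root; used to place simulation studies at a known severity.
    """
    z = np.asarray(z, dtype=float).ravel()
    zs = z - z.mean()
    naive22 = sigma**2 / float(zs @ zs)
    unit = slope_variance_inflation(z, 1.0, v.sigma2_xw, v.K)
    if unit <= 0:
        raise ValueError("no inflation: K is (effectively) the identity")
    return float(np.sqrt(ratio * naive22 / unit))
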