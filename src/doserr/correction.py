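"""Information-matrix correction for shared and unshared Berkson dose error.

With the plug-in score unbiased, Var(theta_hat) decomposes into the naive
piece I_w^{-1} plus a term carrying the dose-error covariance:

    Var(theta_hat) = I_w^{-1} + beta^2 I_w^{-1} M' Var(X|W) M I_w^{-1}

For the Gaussian linear model this simplifies (with M = Z/sigma^2) to

    sigma^2 (Z'Z)^{-1} + beta^2 (Z'Z)^{-1} Z' Var(X|W) Z (Z'Z)^{-1}

Both paths are implemented and are numerically identical.  The correction
vanishes at beta = 0, which is why the ordinary score test of beta = 0 keeps
its size under shared error and is provided here unmodified.

The middle quadratic form M' Var(X|W) M is a p x p matrix however large the
cohort, and accumulates blockwise so the N x N covariance never has to be
materialised at once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .realizations import DoseUncertaintyModel
from .risk_models import OutcomeData, RiskModelFit, fit_null

__all__ = [
    "CorrectedInference",
    "OLSDiagnostics",
    "corrected_covariance",
    "gaussian_corrected_covariance",
    "blockwise_mvm",
    "expected_ols_variance",
    "slope_variance_inflation",
    "wald_ci",
    "score_test_null",
    "ols_diagnostics",
]

logger = logging.getLogger(__name__)

_COND_WARN = 1e12


@dataclass
class CorrectedInference:
    param_names: tuple[str, ...]
    theta: np.ndarray
    naive_cov: np.ndarray
    corrected_cov: np.ndarray
    beta_used: float
    level: float
    ci_naive: np.ndarray      # p x 2
    ci_corrected: np.ndarray  # p x 2
    inflation_22: float | None = None  # gaussian slope-variance inflation
    score_stat: float | None = None
    score_pvalue: float | None = None

    @property
    def naive_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.naive_cov))

    @property
    def corrected_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.corrected_cov))

    def to_dict(self) -> dict:
        out = {
            "params": {
                name: {
                    "estimate": float(self.theta[i]),
                    "naive_se": float(self.naive_se[i]),
                    "corrected_se": float(self.corrected_se[i]),
                    "ci_naive": [float(x) for x in self.ci_naive[i]],
                    "ci_corrected": [float(x) for x in self.ci_corrected[i]],
                }
                for i, name in enumerate(self.param_names)
            },
            "level": self.level,
            "beta_used": self.beta_used,
        }
        if self.score_stat is not None:
            out["score_stat"] = self.score_stat
            out["score_pvalue"] = self.score_pvalue
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


@dataclass
class OLSDiagnostics:
    centered_dose: np.ndarray
    expected_ols_cov: np.ndarray
    inflation: float


def _sym_inv(a: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(a)
    if cond > _COND_WARN:
        logger.warning("information matrix condition number %.3g", cond)
    # symmetric factorization; inverse via Cholesky of the (jittered-free) matrix
    try:
        c = np.linalg.cholesky(a)
        inv_c = np.linalg.inv(c)
        return inv_c.T @ inv_c
    except np.linalg.LinAlgError as exc:
        raise ValueError("information matrix is not positive definite") from exc


def corrected_covariance(
    fit: RiskModelFit,
    v: DoseUncertaintyModel,
    beta: float | None = None,
    level: float = 0.95,
) -> CorrectedInference:
    """Corrected Var(theta_hat) = I_w^{-1} + b^2 I_w^{-1} M'Var(X|W)M I_w^{-1}.

    ``beta`` defaults to the fitted slope; supply an external value for
    design-stage studies.  Subject/record alignment between the fit and the
    uncertainty model is checked by id when both carry ids.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if fit.M.shape[0] != v.n_subjects:
        raise ValueError(
            f"fit has {fit.M.shape[0]} records but Var(X|W) has {v.n_subjects}"
        )
    if beta is None:
        beta = fit.beta
    naive = _sym_inv(fit.information)
    middle = v.quadratic_form(fit.M)
    corrected = naive + beta**2 * naive @ middle @ naive
    ci_naive = np.array(
        [wald_ci(fit.theta[i], naive[i, i], level) for i in range(len(fit.theta))]
    )
    ci_corrected = np.array(
        [wald_ci(fit.theta[i], corrected[i, i], level) for i in range(len(fit.theta))]
    )
    inflation = None
    if fit.spec.family == "gaussian_linear" and v.K is not None:
        inflation = slope_variance_inflation(v.mean_dose, beta, v.sigma2_xw, v.K)
    return CorrectedInference(
        param_names=fit.param_names,
        theta=fit.theta,
        naive_cov=naive,
        corrected_cov=corrected,
        beta_used=float(beta),
        level=level,
        ci_naive=ci_naive,
        ci_corrected=ci_corrected,
        inflation_22=inflation,
    )


def gaussian_corrected_covariance(
    z_design: np.ndarray,
    sigma2: float,
    beta: float,
    cov_xw: np.ndarray,
) -> np.ndarray:
    """Gaussian closed form: s^2 (Z'Z)^-1 + b^2 (Z'Z)^-1 Z'VZ (Z'Z)^-1."""
    z = np.asarray(z_design, dtype=float)
    ztz_inv = _sym_inv(z.T @ z)
    zvz = z.T @ cov_xw @ z
    return sigma2 * ztz_inv + beta**2 * ztz_inv @ zvz @ ztz_inv


def blockwise_mvm(
    m_blocks: Sequence[np.ndarray],
    v_blocks: Iterable[tuple[int, int, np.ndarray]],
) -> np.ndarray:
    """Accumulate M' Var(X|W) M = sum_ij M_i' V_ij M_j from sub-matrices.

    ``m_blocks`` partitions the rows of M in order; ``v_blocks`` yields
    (i, j, V_ij) triples for the nonzero covariance blocks (omitted blocks are
    zero).  Each V_ij is consumed once and can be discarded by the caller:
    memory stays bounded by the largest block, never N x N.
    """
    m_blocks = [np.atleast_2d(np.asarray(m, dtype=float)) for m in m_blocks]
    if not m_blocks:
        raise ValueError("empty partition of M")
    p = m_blocks[0].shape[1]
    out = np.zeros((p, p))
    for i, j, vij in v_blocks:
        vij = np.atleast_2d(np.asarray(vij, dtype=float))
        if vij.shape != (m_blocks[i].shape[0], m_blocks[j].shape[0]):
            raise ValueError(
                f"block ({i},{j}) has shape {vij.shape}, expected "
                f"({m_blocks[i].shape[0]}, {m_blocks[j].shape[0]})"
            )
        out += m_blocks[i].T @ vij @ m_blocks[j]
    return out


def expected_ols_variance(
    z: np.ndarray,
    sigma2: float,
    beta: float,
    sigma2_xw: float,
    k: np.ndarray,
) -> np.ndarray:
    """Expected value of the usual OLS covariance estimator under shared
    Berkson error:

        s^2 (Z'Z)^-1 + (b^2 s_xw^2 / (n-2)) (Z'Z)^-1 [tr K - tr{(Z'Z)^-1 Z'KZ}]

    With K = I the bracket equals n - 2, recovering the homogeneous-error
    expectation (s^2 + b^2 s_xw^2)(Z'Z)^-1.  ``z`` may be the dose vector or
    the full [1, Z] design matrix.
    """
    zd = _as_design(z)
    n = zd.shape[0]
    if n <= 2:
        raise ValueError("need n > 2")
    ztz_inv = _sym_inv(zd.T @ zd)
    zkz = zd.T @ k @ zd
    bracket = float(np.trace(k) - np.trace(ztz_inv @ zkz))
    return sigma2 * ztz_inv + (beta**2 * sigma2_xw / (n - 2)) * bracket * ztz_inv


def slope_variance_inflation(
    z: np.ndarray, beta: float, sigma2_xw: float, k: np.ndarray
) -> float:
    """Inflation of the slope variance over what OLS reports, i.e. the (2,2)
    element of (true variance) - (expected OLS estimate):

        b^2 s_xw^2 / (Z*'Z*) [ (Z*'KZ*/Z*'Z*)(1 + 1/(n-2)) - tr K/(n-2)
                               + 1'K1/(n(n-2)) ]

    with Z* = Z - Zbar.  Zero when b = 0, when s_xw^2 = 0, or when K = I
    (homogeneous independent Berkson error leaves OLS standard errors valid).
    """
    z = np.asarray(z, dtype=float).ravel()
    n = z.shape[0]
    if n <= 2:
        raise ValueError("need n > 2")
    zs = z - z.mean()
    zz = float(zs @ zs)
    if zz == 0:
        raise ValueError("constant dose vector: slope undefined")
    zkz = float(zs @ k @ zs)
    ones = np.ones(n)
    oko = float(ones @ k @ ones)
    bracket = (zkz / zz) * (1.0 + 1.0 / (n - 2)) - np.trace(k) / (n - 2) + oko / (
        n * (n - 2)
    )
    return float(beta**2 * sigma2_xw / zz * bracket)


def wald_ci(estimate: float, variance: float, level: float = 0.95) -> tuple[float, float]:
    """estimate +/- z_{1-(1-level)/2} sqrt(variance)  (1.96 at the 95% level)."""
    if variance < 0:
        raise ValueError("negative variance")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    zq = stats.norm.ppf(1 - (1 - level) / 2)
    half = zq * np.sqrt(variance)
    return float(estimate - half), float(estimate + half)


def score_test_null(
    fit_under_null: RiskModelFit, d: OutcomeData | None = None
) -> tuple[float, float]:
    """Score test of beta = 0: S_w' I_w^{-1} S_w at the constrained MLE,
    referred to chi^2_1.

    Because the dose-error term of the corrected variance vanishes at
    beta = 0, this is the ordinary score test: no dosimetry-uncertainty input
    is needed and shared error does not affect its asymptotic size.
    """
    s = fit_under_null.score
    info = fit_under_null.information
    try:
        stat = float(s @ np.linalg.solve(info, s))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular information matrix in score test") from exc
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=1))


def score_test(family: str, d: OutcomeData) -> tuple[float, float]:
    """Convenience wrapper: fit the null model, then run the score test."""
    return score_test_null(fit_null(family, d), d)


def ols_diagnostics(
    z: np.ndarray, sigma2: float, beta: float, sigma2_xw: float, k: np.ndarray
) -> OLSDiagnostics:
    z = np.asarray(z, dtype=float).ravel()
    return OLSDiagnostics(
        centered_dose=z - z.mean(),
        expected_ols_cov=expected_ols_variance(z, sigma2, beta, sigma2_xw, k),
        inflation=slope_variance_inflation(z, beta, sigma2_xw, k),
    )


def _as_design(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        return np.column_stack([np.ones(z.shape[0]), z])
    return z
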