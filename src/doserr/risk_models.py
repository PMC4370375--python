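"""Naive ("plug-in mean dose") risk models: Gaussian linear, linear Poisson,
and the linear excess-relative-risk (ERR) Poisson model.

Each fit substitutes the mean dose Z for unknown true dose X.  Under the
Berkson contract E(X|W) = Z the plug-in score is unbiased, so the point
estimates are asymptotically valid; the naive information I_w, however,
understates Var(theta_hat) away from the null.  This module exposes, for each
family, the score S_w, the expected information I_w, and the N x p matrix M
for which E(S_w | X) = c + beta M'X -- the three ingredients of the variance
correction in :mod:`doserr.correction`.

Model families
--------------
gaussian_linear : E(Y_i) = a0 + b Z_i, Var(Y_i) = sigma^2
poisson_linear  : Y_i ~ Poisson(t_i (a0 + b Z_i))      (t_i person-time offset)
err_poisson     : Y_i ~ Poisson(t_i exp(a0 + a1 A_i) (1 + b Z_i exp(a2 C_i)))
                  A modifies background rates, C modifies the excess; b is the
                  ERR per unit dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RiskModelSpec",
    "OutcomeData",
    "RiskModelFit",
    "ConvergenceError",
    "fit_gaussian_ols",
    "fit_poisson_linear",
    "fit_err",
    "fit_null",
    "information_matrix",
    "m_matrix",
    "score_vector",
    "log_likelihood",
    "load_outcomes",
]

FAMILIES = ("gaussian_linear", "poisson_linear", "err_poisson")


class ConvergenceError(RuntimeError):
    """Fisher scoring failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[np.ndarray]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class RiskModelSpec:
    family: str
    uses_background_covariates: bool = False
    uses_modifiers: bool = False
    lag: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != "err_poisson" and (
            self.uses_background_covariates or self.uses_modifiers
        ):
            raise ValueError("A/C covariates are only supported by err_poisson")

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.family != "err_poisson":
            return ("alpha0", "beta")
        names = ["alpha0"]
        if self.uses_background_covariates:
            names.append("alpha1")
        if self.uses_modifiers:
            names.append("alpha2")
        names.append("beta")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


@dataclass
class OutcomeData:
    """Outcomes aligned with mean dose per record.

    ``offset`` is person-time for the Poisson families (defaults to 1);
    ``background`` (A) and ``modifier`` (C) enter the ERR family only.
    """

    y: np.ndarray
    dose: np.ndarray
    offset: np.ndarray | None = None
    background: np.ndarray | None = None
    modifier: np.ndarray | None = None
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        n = self.y.shape[0]
        if self.dose.shape[0] != n:
            raise ValueError("dose and outcome lengths differ")
        for name in ("offset", "background", "modifier"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape[0] != n:
                    raise ValueError(f"{name} length differs from outcomes")
                setattr(self, name, v)
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids, dtype=object)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def t(self) -> np.ndarray:
        return self.offset if self.offset is not None else np.ones(self.n)

    @property
    def a(self) -> np.ndarray:
        return self.background if self.background is not None else np.zeros(self.n)

    @property
    def c(self) -> np.ndarray:
        return self.modifier if self.modifier is not None else np.zeros(self.n)


@dataclass
class RiskModelFit:
    spec: RiskModelSpec
    theta: np.ndarray
    score: np.ndarray
    information: np.ndarray
    M: np.ndarray
    converged: bool
    n_iter: int
    sigma2: float | None = None  # residual variance (gaussian only)
    n: int = 0
    param_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def beta_index(self) -> int:
        return len(self.theta) - 1

    @property
    def beta(self) -> float:
        return float(self.theta[-1])


def load_outcomes(
    path: str | Path,
    y: str = "y",
    dose: str = "dose",
    offset: str | None = None,
    background: str | None = None,
    modifier: str | None = None,
    id_col: str | None = "id",
    delimiter: str = ",",
) -> OutcomeData:
    """Read a delimited outcome table; column roles are named, not positional."""
    df = pd.read_csv(path, delimiter=delimiter)
    def col(name):
        return df[name].to_numpy() if name is not None and name in df.columns else None
    return OutcomeData(
        y=df[y].to_numpy(dtype=float),
        dose=df[dose].to_numpy(dtype=float),
        offset=col(offset),
        background=col(background),
        modifier=col(modifier),
        subject_ids=col(id_col),
    )


# ---------------------------------------------------------------------------
# Family internals: mean, dmu/dtheta, naive variance Var*(Y|Z)
# ---------------------------------------------------------------------------

def _design(d: OutcomeData) -> np.ndarray:
    return np.column_stack([np.ones(d.n), d.dose])


def _mu_grad(spec: RiskModelSpec, theta: np.ndarray, d: OutcomeData):
    """Return (mu, dmu/dtheta as n x p) for the Poisson families."""
    t = d.t
    if spec.family == "poisson_linear":
        a0, b = theta
        mu = t * (a0 + b * d.dose)
        grad = np.column_stack([t, t * d.dose])
        return mu, grad
    if spec.family == "err_poisson":
        a0 = theta[0]
        k = 1
        a1 = theta[k] if spec.uses_background_covariates else 0.0
        k += spec.uses_background_covariates
        a2 = theta[k] if spec.uses_modifiers else 0.0
        b = theta[-1]
        ezc = np.exp(a2 * d.c)
        eta = 1.0 + b * d.dose * ezc
        base = t * np.exp(a0 + a1 * d.a)
        mu = base * eta
        cols = [mu]
        if spec.uses_background_covariates:
            cols.append(mu * d.a)
        if spec.uses_modifiers:
            cols.append(base * b * d.dose * d.c * ezc)
        cols.append(base * d.dose * ezc)
        return mu, np.column_stack(cols)
    raise ValueError(f"no Poisson mean for family {spec.family!r}")


def score_vector(
    spec: RiskModelSpec, theta: np.ndarray, d: OutcomeData, sigma2: float | None = None
) -> np.ndarray:
    """Naive score S_w at theta (log-likelihood gradient with Z plugged in)."""
    theta = np.asarray(theta, dtype=float)
    if spec.family == "gaussian_linear":
        if sigma2 is None:
            raise ValueError("gaussian score needs sigma2")
        z = _design(d)
        return z.T @ (d.y - z @ theta) / sigma2
    mu, grad = _mu_grad(spec, theta, d)
    _check_admissible(mu)
    return grad.T @ ((d.y - mu) / mu)


def information_matrix(
    spec: RiskModelSpec, theta: np.ndarray, d: OutcomeData, sigma2: float | None = None
) -> np.ndarray:
    """Expected information I_w = -E d2l/dtheta2 at theta.

    gaussian: (1/sigma^2) Z'Z; Poisson families: sum_i (dmu_i)(dmu_i)'/mu_i
    (for the ERR model this is sum_i mu_i v_i v_i' with v = dlog mu/dtheta).
    """
    theta = np.asarray(theta, dtype=float)
    if spec.family == "gaussian_linear":
        if sigma2 is None:
            raise ValueError("gaussian information needs sigma2")
        z = _design(d)
        return z.T @ z / sigma2
    mu, grad = _mu_grad(spec, theta, d)
    _check_admissible(mu)
    return (grad / mu[:, None]).T @ grad


def m_matrix(
    spec: RiskModelSpec, theta: np.ndarray, d: OutcomeData, sigma2: float | None = None
) -> np.ndarray:
    """N x p matrix M with E(S_w | X) = c + beta M'X.

    Row i is (d E(Y_i|X)/dX_i) / beta times (dmu_i/dtheta)/Var*(Y_i|Z_i):
    gaussian -- Z/sigma^2; poisson_linear -- t_i (t_i, t_i Z_i)/mu_i;
    err -- t_i exp(a0 + a1 A_i + a2 C_i) v_i.
    """
    theta = np.asarray(theta, dtype=float)
    if spec.family == "gaussian_linear":
        if sigma2 is None:
            raise ValueError("gaussian M needs sigma2")
        return _design(d) / sigma2
    mu, grad = _mu_grad(spec, theta, d)
    _check_admissible(mu)
    v = grad / mu[:, None]
    if spec.family == "poisson_linear":
        return v * d.t[:, None]
    # err_poisson: dE(Y_i|X)/dX_i = beta t_i exp(a0 + a1 A_i + a2 C_i)
    a0 = theta[0]
    k = 1
    a1 = theta[k] if spec.uses_background_covariates else 0.0
    k += spec.uses_background_covariates
    a2 = theta[k] if spec.uses_modifiers else 0.0
    scale = d.t * np.exp(a0 + a1 * d.a + a2 * d.c)
    return v * scale[:, None]


def log_likelihood(
    spec: RiskModelSpec, theta: np.ndarray, d: OutcomeData, sigma2: float | None = None
) -> float:
    """Naive log likelihood (Poisson families drop the log y! constant)."""
    theta = np.asarray(theta, dtype=float)
    if spec.family == "gaussian_linear":
        z = _design(d)
        resid = d.y - z @ theta
        return float(-0.5 * d.n * np.log(2 * np.pi * sigma2) - 0.5 * resid @ resid / sigma2)
    mu, _ = _mu_grad(spec, theta, d)
    _check_admissible(mu)
    return float(np.sum(d.y * np.log(mu) - mu))


def _check_admissible(mu: np.ndarray) -> None:
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("inadmissible parameters: nonpositive fitted mean")


# ---------------------------------------------------------------------------
# Fitters
# ---------------------------------------------------------------------------

def fit_gaussian_ols(d: OutcomeData) -> RiskModelFit:
    """OLS of Y on [1, Z]; sigma2 estimated as RSS/(n-2)."""
    spec = RiskModelSpec("gaussian_linear")
    z = _design(d)
    if d.n <= 2:
        raise ValueError("need n > 2 records for OLS with intercept and slope")
    if np.linalg.matrix_rank(z) < 2:
        raise ValueError("rank-deficient design (constant dose?)")
    theta, _, _, _ = np.linalg.lstsq(z, d.y, rcond=None)
    resid = d.y - z @ theta
    sigma2 = float(resid @ resid / (d.n - 2))
    if sigma2 > 0:
        info = z.T @ z / sigma2
        m = z / sigma2
        score = z.T @ resid / sigma2
    else:  # perfect fit: information is unbounded, leave it out
        info = np.full((2, 2), np.inf)
        m = np.full_like(z, np.inf)
        score = np.zeros(2)
    return RiskModelFit(
        spec=spec, theta=theta, score=score, information=info, M=m,
        converged=True, n_iter=0, sigma2=sigma2, n=d.n, param_names=spec.param_names,
    )


def _fisher_scoring(
    spec: RiskModelSpec,
    d: OutcomeData,
    init: np.ndarray,
    tol: float,
    max_iter: int,
    score_tol: float = 1e-6,
    max_halvings: int = 20,
    fixed: Sequence[int] = (),
) -> tuple[np.ndarray, int, list[np.ndarray]]:
    """Fisher scoring with step-halving to keep fitted means admissible.

    ``fixed`` indexes parameters held at their initial value (for null fits).
    """
    theta = np.asarray(init, dtype=float).copy()
    free = np.array([i for i in range(len(theta)) if i not in set(fixed)])
    trace = [theta.copy()]
    for it in range(1, max_iter + 1):
        s = score_vector(spec, theta, d)
        info = information_matrix(spec, theta, d)
        sf = s[free]
        inff = info[np.ix_(free, free)]
        try:
            step = np.linalg.solve(inff, sf)
        except np.linalg.LinAlgError:
            # the modifier column of I_w vanishes identically at beta = 0;
            # a minimum-norm step moves beta first, after which the full
            # information is regular again
            step = np.linalg.lstsq(inff, sf, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            raise ConvergenceError("non-finite scoring step", trace)
        scale = 1.0
        for _ in range(max_halvings + 1):
            cand = theta.copy()
            cand[free] = theta[free] + scale * step
            try:
                mu, _ = _mu_grad(spec, cand, d)
                _check_admissible(mu)
                break
            except ValueError:
                scale *= 0.5
        else:
            raise ConvergenceError(
                "step-halving failed to keep fitted means positive", trace
            )
        rel = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), 1.0))
        theta = cand
        trace.append(theta.copy())
        if rel < tol:
            s = score_vector(spec, theta, d)
            if np.max(np.abs(s[free])) < score_tol * max(1.0, float(np.sum(d.y))):
                return theta, it, trace
    raise ConvergenceError(f"no convergence after {max_iter} iterations", trace)


def fit_poisson_linear(
    d: OutcomeData,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RiskModelFit:
    """Linear-link Poisson fit, mean t_i (a0 + b Z_i), by Fisher scoring."""
    spec = RiskModelSpec("poisson_linear")
    if np.any(d.y < 0):
        raise ValueError("Poisson outcomes must be nonnegative")
    if not np.all(d.y == 0) and np.ptp(d.dose) == 0:
        raise ValueError("dose has no variation; slope not identifiable")
    if np.all(d.y == 0):
        raise ValueError("all outcomes zero: boundary of the parameter space")
    if init is None:
        init = np.array([float(np.sum(d.y) / np.sum(d.t)), 0.0])
    theta, n_iter, _ = _fisher_scoring(spec, d, init, tol, max_iter)
    return _finish_poisson_fit(spec, theta, d, n_iter)


def fit_err(
    d: OutcomeData,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    use_background: bool | None = None,
    use_modifier: bool | None = None,
) -> RiskModelFit:
    """Linear excess-relative-risk Poisson fit by Fisher scoring.

    a1 (background) and a2 (modifier) are included only when the
    corresponding covariate is supplied (or explicitly requested).
    """
    if use_background is None:
        use_background = d.background is not None
    if use_modifier is None:
        use_modifier = d.modifier is not None
    spec = RiskModelSpec("err_poisson", use_background, use_modifier)
    if np.any(d.y < 0):
        raise ValueError("Poisson outcomes must be nonnegative")
    if np.all(d.y == 0):
        raise ValueError("all outcomes zero: boundary of the parameter space")
    if use_modifier and np.ptp(d.c) == 0:
        raise ValueError("modifier C is constant: alpha2 not identifiable")
    if init is None:
        init = np.zeros(spec.n_params)
        init[0] = float(np.log(np.sum(d.y) / np.sum(d.t)))
    theta, n_iter, _ = _fisher_scoring(spec, d, init, tol, max_iter)
    return _finish_poisson_fit(spec, theta, d, n_iter)


def _finish_poisson_fit(spec, theta, d, n_iter) -> RiskModelFit:
    return RiskModelFit(
        spec=spec,
        theta=theta,
        score=score_vector(spec, theta, d),
        information=information_matrix(spec, theta, d),
        M=m_matrix(spec, theta, d),
        converged=True,
        n_iter=n_iter,
        n=d.n,
        param_names=spec.param_names,
    )


def fit_null(family: str, d: OutcomeData) -> RiskModelFit:
    """Fit with the slope constrained to beta = 0 (for the score test).

    For the ERR family the modifier coefficient a2 is dropped: its score and
    information vanish identically at beta = 0.
    """
    if family == "gaussian_linear":
        spec = RiskModelSpec("gaussian_linear")
        a0 = float(np.mean(d.y))
        theta = np.array([a0, 0.0])
        resid = d.y - a0
        sigma2 = float(resid @ resid / (d.n - 1))
        # a perfect null fit has zero residual variance; the score is exactly
        # zero, so any positive scale gives the right (zero) test statistic
        s2 = sigma2 if sigma2 > 0 else 1.0
        return RiskModelFit(
            spec=spec, theta=theta,
            score=score_vector(spec, theta, d, s2),
            information=information_matrix(spec, theta, d, s2),
            M=m_matrix(spec, theta, d, s2),
            converged=True, n_iter=0, sigma2=sigma2, n=d.n,
            param_names=spec.param_names,
        )
    if family == "poisson_linear":
        spec = RiskModelSpec("poisson_linear")
        theta = np.array([float(np.sum(d.y) / np.sum(d.t)), 0.0])
        return _finish_poisson_fit(spec, theta, d, 0)
    if family == "err_poisson":
        use_a = d.background is not None
        spec = RiskModelSpec("err_poisson", use_a, False)
        init = np.zeros(spec.n_params)
        init[0] = float(np.log(np.sum(d.y) / np.sum(d.t)))
        beta_ix = spec.n_params - 1
        theta, n_iter, _ = _fisher_scoring(
            spec, d, init, tol=1e-10, max_iter=100, fixed=(beta_ix,)
        )
        return _finish_poisson_fit(spec, theta, d, n_iter)
    raise ValueError(f"unknown family {family!r}")
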