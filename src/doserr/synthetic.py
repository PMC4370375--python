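"""Synthetic dosimetry systems and outcomes with known ground truth.

Emulates the output of a Monte-Carlo dose-reconstruction program ("complex
dosimetry system"): L joint cohort dose realizations in which subjects in the
same sharing group (shipmates, same test, same island...) co-vary through a
common multiplicative error factor, plus outcome generators for the three
risk-model families, plus an AVS-like point-dose + correlation-triplet
scenario.

Error structure: true dose X_i = Zbar_i * G_g(i) * U_i with independent
lognormal factors of unit mean -- G shared within group (coefficient of
variation cv_shared), U per subject (cv_unshared) -- optionally plus additive
Gaussian noise.  Unit means preserve the Berkson contract E(X|W) = Zbar, and
realizations X^r are drawn i.i.d. from the same conditional law as X, so the
empirical between-realization covariance estimates the analytic one:

    Cov(X_i, X_j | W) = Zbar_i Zbar_j * s_ij,
    s_ii = (1+cv_sh^2)(1+cv_un^2) - 1 (+ additive variance on the diagonal),
    s_ij = cv_sh^2 for i != j in the same group, 0 across groups.

What this generator does not emulate: physically realistic transport of
radionuclides, realization-to-realization changes in sharing structure, or
classical error in dose-determinant inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .realizations import DoseRealizations, DoseUncertaintyModel
from .risk_models import OutcomeData, RiskModelSpec, _mu_grad

__all__ = [
    "DosimetryConfig",
    "OutcomeConfig",
    "SimulatedDosimetry",
    "simulate_dosimetry_system",
    "simulate_outcomes",
    "simulate_avs_like",
    "sample_true_doses",
    "assign_groups",
    "load_scenario",
    "default_scenario_path",
]


@dataclass
class DosimetryConfig:
    n_subjects: int
    L: int = 100
    cv_shared: float = 0.3
    cv_unshared: float = 0.3
    additive_sd: float = 0.0
    base_dose_median: float = 0.1
    base_dose_gsd: float = 2.5
    groups: np.ndarray | None = None  # one label per subject; None = all singletons
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.L < 1:
            raise ValueError("need n_subjects >= 1 and L >= 1")
        if min(self.cv_shared, self.cv_unshared, self.additive_sd) < 0:
            raise ValueError("error magnitudes must be nonnegative")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
            if self.groups.shape[0] != self.n_subjects:
                raise ValueError("groups must assign every subject")


@dataclass
class OutcomeConfig:
    family: str = "gaussian_linear"
    theta: Sequence[float] = (0.0, 1.0)
    sigma: float = 1.0  # gaussian residual SD
    seed: int = 0


@dataclass
class SimulatedDosimetry:
    base_dose: np.ndarray          # Zbar = E(X|W)
    true_dose: np.ndarray          # one draw of X
    realizations: DoseRealizations
    covariance: np.ndarray         # analytic Var(X|W)
    groups: np.ndarray

    def uncertainty_model(self, analytic: bool = True) -> DoseUncertaintyModel:
        """Analytic Var(X|W) about the known Zbar (the oracle), or use
        :func:`doserr.realizations.empirical_covariance` on ``realizations``
        for the estimated version."""
        if not analytic:
            from .realizations import empirical_covariance

            return empirical_covariance(self.realizations, sharing=self.groups)
        return DoseUncertaintyModel(
            self.realizations.subject_ids, self.base_dose, self.covariance,
            groups=self.groups,
        )


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """exp(N(-s^2/2, s)) with s^2 = log(1+cv^2): mean 1, coefficient of
    variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=size)


def assign_groups(
    n: int, frac_grouped: float, group_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Group labels: ~frac_grouped of subjects in sharing groups of
    ``group_size``; the rest are singletons.  Grouped subjects are a random
    subset."""
    if not 0 <= frac_grouped <= 1:
        raise ValueError("frac_grouped must be in [0, 1]")
    n_grouped = int(round(n * frac_grouped / group_size)) * group_size
    labels = np.array([f"s{i}" for i in range(n)], dtype=object)
    member = rng.choice(n, size=n_grouped, replace=False)
    for k in range(n_grouped // group_size):
        for i in member[k * group_size : (k + 1) * group_size]:
            labels[i] = f"g{k}"
    return labels


def _analytic_covariance(cfg: DosimetryConfig, zbar: np.ndarray, groups) -> np.ndarray:
    s_diag = (1 + cfg.cv_shared**2) * (1 + cfg.cv_unshared**2) - 1
    same = groups[:, None] == groups[None, :]
    s = np.where(same, cfg.cv_shared**2, 0.0)
    np.fill_diagonal(s, s_diag)
    cov = s * np.outer(zbar, zbar)
    if cfg.additive_sd > 0:
        cov = cov + cfg.additive_sd**2 * np.eye(cfg.n_subjects)
    return cov


def simulate_dosimetry_system(cfg: DosimetryConfig) -> SimulatedDosimetry:
    """Draw base doses, one true-dose vector, and L realizations.

    True dose and every realization are i.i.d. draws from the same
    conditional law given the latent base doses, so any statistic has the
    same distribution computed on X or on X^r.  Identical seeds give
    bit-identical output; sub-streams are derived per component so that e.g.
    outcomes can be varied while doses stay fixed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_base, rng_true, rng_real = (np.random.default_rng(s) for s in ss.spawn(3))

    zbar = rng_base.lognormal(
        mean=np.log(cfg.base_dose_median), sigma=np.log(cfg.base_dose_gsd),
        size=cfg.n_subjects,
    )
    groups = (
        cfg.groups
        if cfg.groups is not None
        else np.array([f"s{i}" for i in range(cfg.n_subjects)], dtype=object)
    )
    uniq = list(dict.fromkeys(groups.tolist()))
    gidx = np.array([uniq.index(g) for g in groups])

    def draw(rng: np.random.Generator, n_draws: int) -> np.ndarray:
        g = _lognormal_unit_mean(rng, cfg.cv_shared, (len(uniq), n_draws))
        u = _lognormal_unit_mean(rng, cfg.cv_unshared, (cfg.n_subjects, n_draws))
        x = zbar[:, None] * g[gidx] * u
        if cfg.additive_sd > 0:
            x = x + rng.normal(0, cfg.additive_sd, size=x.shape)
        return x

    true = draw(rng_true, 1)[:, 0]
    reals = draw(rng_real, cfg.L)
    ids = np.array([f"s{i:05d}" for i in range(cfg.n_subjects)], dtype=object)
    return SimulatedDosimetry(
        base_dose=zbar,
        true_dose=true,
        realizations=DoseRealizations(ids, reals),
        covariance=_analytic_covariance(cfg, zbar, groups),
        groups=groups,
    )


def sample_true_doses(
    z: np.ndarray,
    cv: float,
    groups: np.ndarray,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Gaussian shared-Berkson draws X = Z + w with Var(w) = C o (cv^2 ZZ'),
    rho = 1 within group: one standard-normal factor per group, scaled by
    cv Z_i.  Matches the point-dose + perfect-correlation construction
    exactly; E(X|Z) = Z.  Returns (n,) or (n, size)."""
    z = np.asarray(z, dtype=float)
    uniq = list(dict.fromkeys(np.asarray(groups, dtype=object).tolist()))
    gidx = np.array([uniq.index(g) for g in np.asarray(groups, dtype=object)])
    shape = (len(uniq),) if size is None else (len(uniq), size)
    e = rng.standard_normal(shape)
    w = cv * (z[:, None] if size is not None else z) * e[gidx]
    return z + w if size is None else z[:, None] + w


def simulate_outcomes(
    x: np.ndarray | OutcomeData,
    cfg: OutcomeConfig,
    offset: np.ndarray | None = None,
    background: np.ndarray | None = None,
    modifier: np.ndarray | None = None,
) -> OutcomeData:
    """Outcomes given true dose: Gaussian Y = a0 + bX + e with Var(e) =
    sigma^2, or independent Poisson counts with the family's mean times the
    person-time offset."""
    if isinstance(x, OutcomeData):
        base = x
        dose = base.dose
        offset, background, modifier = base.offset, base.background, base.modifier
    else:
        dose = np.asarray(x, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    theta = np.asarray(cfg.theta, dtype=float)
    if cfg.family == "gaussian_linear":
        y = theta[0] + theta[-1] * dose + rng.normal(0, cfg.sigma, size=dose.shape)
        return OutcomeData(y=y, dose=dose)
    spec = RiskModelSpec(
        cfg.family,
        uses_background_covariates=(cfg.family == "err_poisson" and background is not None),
        uses_modifiers=(cfg.family == "err_poisson" and modifier is not None),
    )
    d0 = OutcomeData(
        y=np.zeros_like(dose), dose=dose, offset=offset,
        background=background, modifier=modifier,
    )
    mu, _ = _mu_grad(spec, theta, d0)
    if np.any(mu < 0):
        raise ValueError("negative Poisson mean under theta_true")
    y = rng.poisson(mu).astype(float)
    return OutcomeData(
        y=y, dose=dose, offset=offset, background=background, modifier=modifier,
    )


def simulate_avs_like(
    n: int,
    frac_grouped: float = 1.0 / 12.0,
    cv: float = 0.5,
    seed: int = 0,
    group_size: int = 10,
    group_spread: float = 0.1,
    dose_median: float = 0.1,
    dose_gsd: float = 2.5,
):
    """Point doses plus rho = 1 correlation triplets in the style of a
    high-sided compensation-dose cohort.

    Members of a sharing group (shipmates etc.) receive similar doses: a
    common lognormal group base times a small lognormal spread
    (``group_spread`` as GSD-like log-SD), so shared error genuinely co-moves
    within groups.  Returns (subject_ids, doses, triplets, group_labels);
    feeding the first three to
    :func:`doserr.realizations.covariance_from_cv_correlation` builds
    Var(X|W) = C o (cv^2 Z Z').
    """
    ss = np.random.SeedSequence(seed)
    rng_grp, rng_dose = (np.random.default_rng(s) for s in ss.spawn(2))
    groups = assign_groups(n, frac_grouped, group_size, rng_grp)
    ids = np.array([f"v{i:05d}" for i in range(n)], dtype=object)
    doses = np.empty(n)
    for g in dict.fromkeys(groups.tolist()):
        idx = np.where(groups == g)[0]
        base = rng_dose.lognormal(np.log(dose_median), np.log(dose_gsd))
        if len(idx) == 1:
            doses[idx] = base
        else:
            doses[idx] = base * rng_dose.lognormal(0.0, group_spread, size=len(idx))
    triplets = []
    for g in dict.fromkeys(groups.tolist()):
        idx = np.where(groups == g)[0]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                triplets.append((str(ids[idx[a]]), str(ids[idx[b]]), 1.0))
    return ids, doses, triplets, groups


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------

def default_scenario_path() -> Path:
    """The packaged AVS-like default scenario (avs_like.cfg)."""
    return Path(__file__).parent / "scenarios" / "avs_like.cfg"


def load_scenario(path: str | Path | None = None) -> dict:
    """Structured-text (YAML) scenario file with DosimetryConfig /
    OutcomeConfig fields."""
    path = Path(path) if path is not None else default_scenario_path()
    with open(path) as f:
        return yaml.safe_load(f)


def coverage_study(
    n_replicates: int = 2000,
    seed: int = 0,
    n: int = 500,
    frac_grouped: float = 1.0 / 12.0,
    group_size: int = 10,
    cv: float = 0.5,
    sigma: float = 1.0,
    alpha0: float = 0.0,
    beta: float | str = "calibrated",
    inflation_ratio: float = 1.0,
    level: float = 0.95,
) -> dict:
    """Wald-interval coverage under the AVS-like shared-Berkson scenario.

    One fixed cohort (doses Z, perfect within-group correlation, CV ``cv``)
    is drawn from :func:`simulate_avs_like`; each replicate then draws true
    doses X = Z + w with Var(w) = C o (cv^2 ZZ'), Gaussian outcomes
    Y = a0 + bX + e, fits naive OLS on Z, and forms naive (sigma_hat^2
    (Z'Z)^-1) and corrected (Eq.-(5)-style) intervals for the slope.

    ``beta="calibrated"`` places the slope where the shared-error variance
    inflation equals ``inflation_ratio`` times the error-free OLS slope
    variance.  Returns empirical coverage percentages and the inputs used.
    """
    from .correction import gaussian_corrected_covariance, wald_ci
    from .design import calibrate_slope_for_inflation
    from .realizations import covariance_from_cv_correlation
    from .risk_models import OutcomeData, fit_gaussian_ols

    ss = np.random.SeedSequence(seed)
    seed_scenario, seed_reps = ss.spawn(2)
    ids, z, triplets, groups = simulate_avs_like(
        n, frac_grouped=frac_grouped, cv=cv, group_size=group_size,
        seed=seed_scenario.generate_state(1)[0] % (2**31),
    )
    v = covariance_from_cv_correlation(z, cv, triplets, subject_ids=ids)
    if beta == "calibrated":
        beta = calibrate_slope_for_inflation(z, v, sigma, ratio=inflation_ratio)
    beta = float(beta)

    zd = np.column_stack([np.ones(n), z])
    ztz_inv = np.linalg.inv(zd.T @ zd)
    # Var(beta_hat) = sigma^2 (Z'Z)^-1 + beta^2 quad; quad is fixed across
    # replicates because Z and Var(X|W) are study constants
    quad = (gaussian_corrected_covariance(zd, 0.0, 1.0, v.covariance))[1, 1]
    naive_unit = ztz_inv[1, 1]

    rng = np.random.default_rng(seed_reps.generate_state(1)[0] % (2**31))
    cover_naive = cover_corr = 0
    for _ in range(n_replicates):
        x = sample_true_doses(z, cv, groups, rng)
        y = alpha0 + beta * x + rng.normal(0, sigma, size=n)
        fit = fit_gaussian_ols(OutcomeData(y=y, dose=z))
        var_naive = fit.sigma2 * naive_unit
        var_corr = var_naive + fit.beta**2 * quad
        lo, hi = wald_ci(fit.beta, var_naive, level)
        cover_naive += lo <= beta <= hi
        lo, hi = wald_ci(fit.beta, var_corr, level)
        cover_corr += lo <= beta <= hi
    return {
        "coverage_naive_pct": 100.0 * cover_naive / n_replicates,
        "coverage_corrected_pct": 100.0 * cover_corr / n_replicates,
        "beta": beta,
        "n": n,
        "n_replicates": n_replicates,
        "level": level,
    }
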