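# Methods

## Model and assumptions

The package treats the dosimetry system as a black box emitting L joint
cohort dose realizations X¹ … X^L regarded as i.i.d. draws from f(X | W),
the conditional law of true dose given everything known about its
determinants. Averaging gives Z = E(X | W) (estimated by the realization
mean), which converts the problem to Berkson form: X varies around Z with
E(X | Z) = Z. Everything downstream assumes

1. non-differential error — Y ⟂ Z | X;
2. the Berkson contract E(X | W) = Z (classical error in dose-determinant
   *inputs* must have been converted upstream, inside the dosimetry system;
   this package does not deconvolve);
3. a dose-response that is linear in X: Gaussian linear, linear-link
   Poisson, or the linear excess-relative-risk (ERR) Poisson form
   E(Y) = t·e^{α₀+α₁A}(1 + βX e^{α₂C}) with person-time t, background
   covariates A, and excess modifiers C.

Under 1–3 the naive ("plug-in Z") score S_w is unbiased at the true θ, so
naive point estimates and the score test of β = 0 are asymptotically valid.
The naive covariance I_w⁻¹ is not: Var(S_w) = I_w + β² M′ Var(X|W) M, where
M is the N × p matrix with E(S_w | X) = c + β M′X, giving

    Var(θ̂) = I_w⁻¹ + β² I_w⁻¹ M′ Var(X|W) M I_w⁻¹.

Per-family ingredients (t = person-time offset, v = ∂ log μ/∂θ):

| family | I_w | M row i |
|---|---|---|
| Gaussian | (1/σ²) **Z**′**Z** | **Z**ᵢ/σ² |
| Poisson linear | Σ (∂μ)(∂μ)′/μ, μ = t(α₀+βZ) | (tᵢ/(α₀+βZᵢ))·(tᵢ, tᵢZᵢ) |
| ERR Poisson | Σ μ v v′ | tᵢ e^{α₀+α₁Aᵢ+α₂Cᵢ} vᵢ |

For the ERR family vᵢ = (1, Aᵢ, CᵢβZᵢe^{α₂Cᵢ}/ηᵢ, Zᵢe^{α₂Cᵢ}/ηᵢ) with
ηᵢ = 1 + βZᵢe^{α₂Cᵢ}. The M row is derived directly from
∂E(Yᵢ|X)/∂Xᵢ = β tᵢ e^{α₀+α₁Aᵢ+α₂Cᵢ}, so its last entry carries the factor
e^{α₂Cᵢ} twice (once in the prefactor, once in v). Some published displays
of this row omit one e^{α₂C} in the last entry; the derived form is the one
that satisfies the defining linearity E(S_w | X) = c + βM′X (verified
against brute-force score evaluation in the tests). The two coincide
whenever C = 0.

## Gaussian closed forms

With design **Z** = [1, Z]:

- corrected covariance: σ²(**Z**′**Z**)⁻¹ + β²(**Z**′**Z**)⁻¹**Z**′Var(X|W)**Z**(**Z**′**Z**)⁻¹
  (identical to the generic sandwich with M = **Z**/σ²);
- writing Var(X|W) = σ²_{X|W}·K with tr K = N, the expected value of the
  usual OLS covariance estimate σ̂²(**Z**′**Z**)⁻¹ is
  σ²(**Z**′**Z**)⁻¹ + (β²σ²_{X|W}/(n−2))(**Z**′**Z**)⁻¹[tr K − tr{(**Z**′**Z**)⁻¹**Z**′K**Z**}];
- the slope-variance inflation (true minus expected-reported, (2,2) element)
  is (β²σ²_{X|W}/Z*′Z*)[(Z*′KZ*/Z*′Z*)(1+1/(n−2)) − tr K/(n−2) + 1′K1/(n(n−2))],
  Z* = Z − Z̄. It vanishes when β = 0, σ²_{X|W} = 0, or K = I
  (homogeneous independent Berkson error leaves OLS standard errors honest);
  with K = I, E(σ̂²) = σ² + β²σ²_{X|W}.

These identities are asserted to ≤1e−10 relative error on random instances.

## Conventions and numerical choices

- **Covariance divisor.** Var(X|W) uses divisor L (population style); an
  `unbiased=True` flag switches to L−1. At the L of real dosimetry systems
  (10²–10⁴) the difference is immaterial.
- **PSD validation.** Cholesky of V + jitter·I with jitter = 1e−10·tr(V)/N;
  failure is an error, never a silent repair. The exact zero matrix
  (zero-error limit) is accepted.
- **Sharing structure.** When group labels are supplied, cross-group
  covariance entries are forced to exactly zero and quadratic forms
  accumulate per group block (`blockwise_mvm` streams arbitrary block
  partitions; memory is bounded by the largest block). The sharing summary
  counts a subject as shared if any off-diagonal entry exceeds `tol`
  (default 0 — exact nonzero — since the C∘(cv²ZZ′) construction produces
  exact zeros).
- **Fisher scoring.** Convergence when the max relative θ-change < 1e−8 and
  the score is ~0 (∞-norm below 1e−6 scaled by total counts); max 100
  iterations; up to 20 step-halvings keep fitted means positive and
  1 + βZe^{α₂C} > 0. Initial values: Gaussian closed form; Poisson
  (Ȳ/t̄, 0); ERR (log(Ȳ/t̄), 0, …, 0). At the ERR start the modifier column
  of I_w vanishes (β = 0), so the first step uses a minimum-norm
  least-squares solve; once β moves off zero the information is regular.
- **β in the correction term** defaults to the fitted slope β̂; an external
  value can be supplied for design studies. The term is exactly zero at
  β = 0, so corrected and naive inference coincide under the null.
- **Score test.** S′I⁻¹S at the constrained MLE (β = 0), referred to χ²₁.
  The Gaussian null variance estimate is RSS₀/(n−1) (degrees of freedom of
  the null model); the statistic is then (n−1)r². For the ERR family the
  modifier coefficient α₂ is dropped under the null — its score and
  information vanish identically at β = 0, making it unidentifiable there.
- **Matrix inversion** via Cholesky; condition numbers above 1e12 are logged
  as warnings.
- **Wald intervals**: θ̂ ± z·SE with z = Φ⁻¹(1−(1−level)/2) (1.96 at 95%).
  Two-sided χ²₁ p-values; no multiplicity adjustment (single-parameter
  method).
- **Overdispersion** is not implemented; the Poisson variance function is
  used as-is.

## Person-year disaggregation

Follow-up is split into half-open [a, a+interval) records (final partial
interval keeps fractional person-time; total person-time is conserved under
any interval width). The event belongs to the record containing its age;
boundary events go to the later interval, and an event exactly at exit to
the last record. The cumulative lagged dose of a record ending at b counts
dose accrued strictly before b − lag, with uniform accrual within each
exposure year — so records ending within `lag` years of first exposure carry
zero dose. (Whether the lag should anchor at the record start, midpoint or
end is not standardised; the end-anchored rule is used and tested, e.g.
annual doses (1,1,1) with lag 2 give record doses (0,0,1).) Poisson ERR on
the disaggregated table equals the piecewise-exponential survival likelihood
on the same grid up to Σ d·log t, a constant in θ; deviances agree to 1e−8
in the tests. The record-level Var(X|W) across realizations automatically
carries within-subject correlation, since cumulative sums share annual
terms. The slope-dilution refinement in which E(X | W) itself drifts with
follow-up time when β > 0 (high-dose subjects leave the risk set faster) is
not modelled; it matters only when exposure-driven events are a large
fraction of the cohort.

## Synthetic data: what it emulates, and not

`simulate_dosimetry_system` draws true dose and realizations i.i.d. from
Xᵢ = Z̄ᵢ·G_{g(i)}·Uᵢ with unit-mean lognormal factors (shared G per group at
`cv_shared`, unshared U at `cv_unshared`; optional additive Gaussian noise).
Unit means preserve E(X|W) = Z̄ exactly, and the analytic covariance
(off-diagonal Z̄ᵢZ̄ⱼcv²_sh within group; diagonal
Z̄ᵢ²[(1+cv²_sh)(1+cv²_un)−1]) is returned as an oracle for the empirical
estimator. Defaults: base doses lognormal (median 0.1 Gy, GSD 2.5), cv 0.3,
L = 100.

The AVS-like scenario (`simulate_avs_like`, packaged in
`scenarios/avs_like.cfg`) emulates a high-sided compensation-dose cohort:
point doses with CV 50% (variance 0.25·dose²), one subject in twelve in a
ρ = 1 sharing group of ~10 (shipmates / same test / same island). Group
members receive similar doses — a common lognormal base times a small
spread (log-SD 0.1) — which is what makes shared error genuinely co-move
within groups and produces the none ≥ unshared ≥ shared power ordering; with
arbitrary within-group dose signs that ordering is not a theorem. The
Gaussian sampler `sample_true_doses` draws X = Z + w with
Var(w) = C∘(cv²ZZ′) exactly (one standard-normal factor per group scaled by
cv·Zᵢ).

Not emulated: physical transport modelling, realization-dependent sharing
structure, classical input error, negative-dose truncation (the Gaussian
sampler can produce negative true doses at large cv — acceptable for the
Gaussian outcome model it serves).

## Study sizes used in the checks

The coverage study runs 2000 replicates of n = 500 with the slope calibrated
so the shared-error variance inflation equals the error-free OLS slope
variance (a one-line square root, since the inflation is ∝ β²): corrected
95% intervals attain ~95% coverage while naive intervals cover ~84%. The
score-test size check uses 5000 replicates at n = 200; the OLS-expectation
check 10⁵ vectorised replicates at n = 20; parameter recovery one fit at
n = 10⁴ per Poisson family plus 500 replicate fits at n = 1500 for the
corrected-SE-versus-empirical-SD comparison (agreement within 5%, which is
~1.6 standard errors of a 500-replicate SD estimate — the tightest of the
Monte-Carlo checks).

## Known limitations

- Logistic links are out of scope: both the mean and the variance are
  non-linear in the covariates, breaking the linear-score argument. For rare
  outcomes the Poisson ERR model is a close stand-in.
- Linear-quadratic dose response would additionally need Var(X²|W) and
  Cov(X, X²|W); not implemented.
- The correction adjusts variances/intervals away from the null; a corrected
  *test* away from the null is intentionally absent (the null test needs no
  correction).
- Passing synthetic checks demonstrates internal consistency under the
  generator's error structure, not that any particular real dosimetry system
  satisfies E(X|W) = Z.
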