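# Methods

## The transform and the NAP-HL model

The package is built around the CDF map

    T(p; α) = (α^{1 − p^α} − α) / (1 − α),   p ∈ [0, 1], α > 0,

applied to a baseline CDF value `p = H(x)`. `T` is a strictly increasing
bijection of the unit interval for every α (its derivative
`(α log α / (α − 1)) p^{α−1} α^{1−p^α}` is positive), so composing it
with any continuous baseline yields a valid distribution, and the
algebraic inverse

    T⁻¹(u; α) = (1 − log(u(1 − α) + α) / log α)^{1/α}

gives quantiles and inverse-transform sampling for free. The α = 1 case
is a removable singularity with limit `T(p) = p`; the implementation
branches to that limit for |α − 1| < 1e-6 because the naive quotients
lose precision there. Powers of α are always evaluated as
`exp(y·log α)` so the α < 1 branch is handled symmetrically and large α
cannot overflow.

The NAP-HL distribution is this transform applied to the half-logistic
baseline `H(x) = (1 − e^{−θx})/(1 + e^{−θx})`. Parameters and units:

* `alpha` (dimensionless shape, default-free): controls skewness, tail
  weight and the hazard shape; α = 1 is the plain half-logistic model.
* `theta` (rate, units 1/x): pure inverse scale. All quantiles scale as
  1/θ, so skewness and kurtosis are θ-free — a property the test suite
  exploits as an oracle.

Support convention: densities live on x > 0; `cdf(x ≤ 0) = 0`. The
quantile at u = 1 is reported as `+inf` rather than raising. Baseline
CDF values that stray outside [0, 1] by floating error (EDF-based
estimators routinely produce `1 + 1e-16`) are clamped, with a debug log
record; genuine violations raise.

## Numerical choices

Moments, incomplete moments, entropies, mean residual life and the
normalisation checks are computed by adaptive Gauss–Kronrod quadrature
on the closed-form density, integrating over `(0, q(1 − 1e-12))` rather
than an infinite interval. The triple-series mixture representation of
the density (expansion indices from `α^{−H^α}`, the `(1−e^{−θx})` power
and the `(1+e^{−θx})` power) is implemented only as an analytic
cross-check with configurable truncation: the two generalised-binomial
series are alternating with terms decaying like `q^{α(k+1)} e^{−θxq}`,
so convergence is hopeless near x = 0 and the check is asserted on
x ∈ [0.5, 5] at truncation order 40, where the truncated series agrees
with the closed form to ~1e-4.

The mode is found by bounded scalar minimisation of `−log pdf` on
`(0, q(0.999))` with tolerance 1e-10. Kurtosis in `moment_summary` is
the raw (non-excess) `μ₄c/σ⁴` convention, matching the reference
property tables; sample kurtosis in `describe` is instead the
bias-corrected excess estimator, which is the convention of the
reference descriptive tables — the two serve different tables and are
documented on each function. `describe` also reports the uncorrected
moment-ratio variants.

The mean-residual-life and mean-waiting-time use the integral
definitions `MRL(t) = ∫_t^∞ S / S(t)` and `MWT(t) = t − φ₁(t)/F(t)` and
are validated through the total-expectation identity
`E X = F(t)(t − MWT(t)) + S(t)(t + MRL(t))`; published series forms for
these quantities are not used (the closed-form route is both simpler
and verifiable).

## Estimation

All seven criteria are expressed through the fitted CDF at the order
statistics, hence invariant to input ordering. Conventions:

* Spacings use `F(x₍₀₎) = 0`, `F(x₍ₙ₊₁₎) = 1`; exact ties are jittered
  by 1e-9 of the sample range with a warning, since spacings of tied
  observations are zero (the MPS objective signals −inf if a spacing
  still vanishes).
* The CvM plotting position is `(2k−1)/(2n)` summed over k = 1..n; the
  least-squares position is `k/(n+1)` with WLS weights
  `(n+1)²(n+2)/(k(n−k+1))`.
* Both Anderson–Darling variants pair `F(x₍ₖ₎)` with `S(x₍ₙ₊₁₋ₖ₎)`,
  the standard index convention for these statistics.
* Optimisation runs over `(log α, log θ)` — positivity without box
  constraints — with Nelder–Mead (numerical gradients only: the
  published analytic score expressions are unreliable) and a small
  multi-start grid α₀ ∈ {0.5, 1.2, 3}, θ₀ = log 3 / median(x) (the
  half-logistic median relation). Monte Carlo replicates use the single
  central start for speed and fall back to the full grid on
  non-convergence.
* `FitResult.loglik` always reports the maximised log-likelihood at the
  returned parameters regardless of the fitting criterion, and
  AIC = 2k − 2ℓ̂; how a report renders signs is a presentation concern.

Competitor models (OFHL, KHL, EHL, MoHL, HL, PoHL) are each a known
G-family composition applied to the half-logistic CDF; their closed-form
CDFs are derived from that structure and cross-validated against
numerical integration of the densities in the tests. The KHL survival
factor `1 − G^α` is formed as `−expm1(α log1p(·))` because it cancels
catastrophically once `G^α` rounds to one, several decades before the
density underflows.

## Goodness of fit

`gof_report` evaluates (not minimises) the classical uncorrected EDF
statistics at the fitted CDF, plus `D = max(k/n − u₍ₖ₎, u₍ₖ₎ − (k−1)/n)`
with the p-value from the exact finite-n one-sample Kolmogorov
distribution (`scipy.stats.kstwo`) — the same small-sample convention
R's `ks.test` applies below n = 100, which is what the reference values
reproduce; the asymptotic series is visibly off at n = 20.

## The Monte Carlo harness

`run_simulation` draws replicate samples by inverse-transform sampling
and summarises each (parameter set, n, method) cell by AB (mean absolute
deviation), MSE and MRE = AB/true, so `AB = true × MRE` holds exactly.
Default study conditions are the three reference parameter sets
(0.65, 0.95), (1.25, 0.45), (2.15, 1.65), sample sizes
25–500 and 1000 replicates. Replicate streams are spawned from the root
seed by a counter-based `SeedSequence` keyed on (set, n, replicate), so
any cell can be recomputed independently and in parallel without
changing results, and every method sees the same replicate samples.
Non-converged fits are retried from the multi-start grid and excluded
with a reported count if they still fail (in practice convergence
failures do not occur at these conditions).

What the generator emulates — i.i.d. complete samples from the exact
model at the study's parameter sets — and what it does not: censoring,
ties from measurement rounding, contamination or model misspecification.
Passing simulation checks therefore demonstrate estimator behaviour
under the model, not robustness on messy field data.

Test problem sizes: the acceptance tests check parameter set I with the
MLE and MPS criteria at n ∈ {25, 50, 100, 250, 500} and 200 replicates,
comparing AB and MSE within three Monte-Carlo standard errors estimated
from the replicate variance; the full grid is available through
`naphl simulate`. One reference cell (MLE, θ, n = 250) is internally
inconsistent with its own neighbours under 1/√n scaling and does not
reproduce at any replicate count; the corresponding check is left
failing deliberately rather than loosening the tolerance.

## Known limitations

* The series expansion is a diagnostic, not a computational route; it
  diverges numerically near the support's lower end and for shapes far
  from 1.
* No censored-data likelihoods, standard errors or interval estimates.
* The MGF is a truncated moment series valid only for |t| < θ.
* Competitor fitting is MLE-only by design; the seven criteria apply to
  the NAP-HL model.
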