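# Methods

`dcemaxent` estimates the arterial input function (AIF) of a DCE-MRI study
*blindly* — from the measured plasma concentration curve itself rather than a
population template — by maximum-entropy (ME) density fitting, and then
estimates the two-compartment kinetic rate constants by Bayesian MAP. This
note records the models, the numerical choices, and what the synthetic tests
do and do not demonstrate.

## Kinetic model

Tissue contrast-agent concentration follows the two-compartment exchange
model

    dCtis/dt = K1 Cp(t) − K2 Ctis(t),  Ctis(0) = 0
    ⇒ Ctis(t) = K1 ∫₀ᵗ Cp(u) e^{−K2 (t−u)} du,

with K1, K2 in min⁻¹ (plasma → extravascular-extracellular space and back).
All kinetics run in minutes internally; curve CSVs use seconds and mM at the
boundary, matching how acquisition protocols are quoted.

The convolution is evaluated by an exact recursion for piecewise-linear
Cp with the exponential kernel (O(n), unconditionally stable, analytic
K2 → 0 limit). Its only error is the linear-interpolation error of Cp
between samples, which is O(Δt²); the test suite verifies the ~4× error drop
under grid halving against a closed-form biexponential oracle.

Integrating the ODE once gives a relation *linear* in (K1, K2):
Ctis(tᵢ) = K1 ∫₀^tᵢ Cp − K2 ∫₀^tᵢ Ctis. Stacking cumulative trapezoid-rule
integrals row-wise yields the design matrix A with C = A·[K1 K2]ᵀ, solved by
ordinary least squares (`llsq_fit`). The LLSQ solution is unconstrained;
negative components are reported as-is with a flag, never silently clipped.
Integration starts at the first sample (curves are assumed to begin at
injection; a pre-injection bolus-arrival delay belongs in the AIF's
`delay_min`, not in extra baseline frames).

## MAP estimation

The observation model is y = A K + ε with ε white Gaussian of variance σ².
The negative log posterior is

    T(K) + α S(K),  T(K) = ‖y − A K‖²/σ²,  S(K) = Σⱼ Kⱼ log Kⱼ,

i.e. a Gaussian likelihood with the classic maximum-entropy regularizer of
image reconstruction as prior on the non-negative rates (0 log 0 := 0). The
prior's functional form and weight are genuinely open design choices here;
we use S as above with default α = 0.01 — small enough to act only as a
non-negativity-respecting stabilizer, and configurable to 0 for the
unpenalized comparison (at α = 0 with an interior optimum the MAP point
coincides with LLSQ, which the tests assert to 1e-6 relative). σ² defaults
to the LLSQ residual estimate RSS/(m−2). Optimization is bounded L-BFGS-B
with the analytic gradient (default) or TLBO with a local polish.

## Maximum-entropy density fitting

Among all densities on a support S satisfying moment constraints
E[ϕₖ(X)] = μₖ, the maximum-entropy one is
f(x) = exp(−Σₖ λₖ ϕₖ(x)). Supported ϕ tags: const, identity, power(p), log,
x·log x. The default constraint set for AIF work is {1, log x, x³}, under
which the ME family contains the Weibull density with shape 3 exactly:

    λ0 = −log(k c⁻ᵏ),  λ1 = −(k−1),  λ2 = c⁻ᵏ

maps Weibull(k, c) onto the multipliers and is algebraically invertible
(k = 1 − λ1, c = λ2^(−1/k)); the worked default (k = 3, c = 1.8498 min)
gives λ0 = 0.7466.

Numerical choices:

- **λ0 elimination.** λ0 = log ∫ exp(−Σ_{k≥1} λₖϕₖ) is computed analytically,
  so normalization holds exactly and only λ1…λN are free unknowns.
- **Quadrature.** Fixed 2001-point composite Simpson on the support, with a
  max-shift inside the exponential (log-sum-exp) so intermediate multipliers
  cannot overflow. Deterministic and testable; every returned density
  integrates to 1 within 1e-6.
- **Support.** The working support defaults to
  [max(1e-6, 0.5·min sample), 1.5·max sample]: log-type functions are
  non-integrable at 0, and the upper margin keeps fitted tails inside the
  integration window. Configurable.
- **Solvers.** The production solver is TLBO minimizing the summed squared
  constraint residuals over a bounded multiplier box (half-width 10 by
  default), stopping early once the residual target is met. The cross-check
  solver is damped Newton on the convex dual ψ(λ) = log Z + λ·μ, whose
  gradient is the constraint residual and whose Hessian is the covariance of
  the ϕ's under the current density. A solve whose max residual exceeds the
  tolerance (default 1e-6) raises, carrying the residual vector — there is
  no silent success, and infeasible constraints take the same path.
- **Moments.** Constraint targets are plain empirical averages of ϕₖ over
  the sample.

### AIF estimation modes

The density being fitted can be read two ways, and both are provided:

- `value_density` (default): the sample is the set of measured plasma
  *concentrations*; the AIF estimate at tᵢ is f(Cp(tᵢ)), rescaled so its
  time integral matches the measured curve's.
- `time_density`: the sample is time points resampled with probability
  ∝ Cp(tᵢ) (n = 2000 by default, seeded); the AIF estimate is
  f(t)·∫Cp dt. For a Weibull-shaped bolus the time-density *is* the
  generating Weibull, which makes this mode the natural closed-loop check.

Concentrations at or below 1e-3 of the curve maximum count as zeros (below
measurement precision) and are excluded from the value sample when log-type
functions are present, with the count logged and recorded in diagnostics.
Without this, the noiseless synthetic bolus tail (values down to ~1e-48 mM,
far below anything a scanner can measure) drives E[log Cp] outside the
attainable range of any density on the working support.

## TLBO

Teaching-learning-based optimization maintains a population of candidate
solutions. Teacher phase: each learner proposes
X + r·(X_teacher − Tf·mean), r ~ U(0,1) per learner, Tf ∈ {1,2}
equiprobable. Learner phase: each learner is paired with a random distinct
partner and steps r·(X_better − X_worse) along the pair difference. Both
phases accept only strict improvements, so the best-so-far trace is monotone
non-increasing (asserted in tests on every run). Proposals are clipped to the
bounds; non-finite objective values are treated as +∞. One phrasing of the
learner step fixes the direction toward the better of the pair; another flips
the sign according to the mover's own rank — for a (learner, partner) pair
these are the same update, so a single rule is implemented. Teacher, mean and
partner values are those at phase entry. There is no duplicate-elimination
step. Stopping: iteration budget, an optional objective target, and an
optional stall window (best improvement < tolerance over 20 iterations);
the stall check is off by default so the budget is explicit.

## Weibull estimators

Six routes to (k, c): empirical power-law (k = (σ/x̄)^−1.086), method of
moments (exact CV equation solved by bracketed root-finding on k ∈ [0.1, 50]
— deliberately *not* the power-law shortcut, so the two methods stay
distinct), profile-likelihood MLE (fixed-point iteration on the k equation),
modified maximum likelihood for binned/frequency data (frequency-weighted
fixed point; invariant to common rescaling of the frequencies), nonlinear
least squares on the CDF against Benard plotting positions
(i − 0.3)/(n + 0.4) via Levenberg–Marquardt in log-parameters, and the exact
multiplier mapping above. Sample standard deviations use the n−1
denominator throughout. All data-driven routes are scale-equivariant in c
and scale-invariant in k (property-tested).

## Synthetic study generator

The generator emulates a breast DCE-MRI protocol: 46 frames every 11.9 s
(span 535.5 s), a Weibull-shaped AIF (k = 3, c = 1.8498 min, amplitude
1 mM·min — a pdf scaled by an amplitude, since a bare pdf has unit area, not
physical concentration), per-patient K1 ~ U(0.1, 1.1) min⁻¹ and
K2 ~ U(0.01, 0.4) min⁻¹ (fixture ranges bracketing typical reported spreads
— not measured values), tissue curves by the exact convolution, and additive
homoscedastic Gaussian noise with sd 5% of each patient's noiseless tissue
peak by default (an absolute-sd mode exists). Noise is unclipped: the model
assumes unbounded Gaussian noise, so slightly negative concentrations can
occur. All truths are drawn before any noise, so ground truth is invariant
to noise settings under a common seed; identical configs reproduce
bit-identical studies.

What the generator does *not* emulate: T1-to-concentration conversion noise
(the conversion formula itself is provided as `concentration_from_T1`),
plasma-curve measurement noise, patient motion, bolus dispersion between
artery and tissue, and partial-volume effects. Passing the recovery tests
therefore shows the estimators are correct and stable under the stated
noise model, not that they are robust to every artefact of real acquisitions.

## Problem sizes used in tests

The packaged checks use the sizes the method is designed around: 46-frame
grids for study-level tests, Δt = 0.01 min grids (901 points) for
discretization-convergence checks, n = 10⁴ samples × 20 seeds for estimator
consistency, 12 patients × 50 seeds for MAP recovery, and 100 seeds for the
optimizer benchmark.

## Known limitations

- The ME value-density route is a heuristic read of blind AIF estimation:
  it models the distribution of concentration values, not the time course,
  and the reconstructed curve f(Cp(t)) inherits that interpretation. The
  time-density mode is the probabilistically clean alternative.
- The entropy prior's weight α is not estimated from data; it is a fixed
  regularization knob.
- Only box constraints in TLBO; no three-parameter (location-shifted)
  Weibull; no censored-data likelihoods; no voxel-wise/spatial modelling.
- Constraint sets are limited to the shipped function tags; trigonometric
  constraints are out of scope.
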