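# dcemaxent

Blind arterial-input-function (AIF) estimation and kinetic-parameter fitting
for dynamic contrast-enhanced MRI (DCE-MRI) concentration-time curves.

## The problem

Quantitative DCE-MRI models the leakage of a gadolinium contrast agent from
plasma into tissue with the two-compartment exchange model

    dCtis/dt = K1 Cp(t) − K2 Ctis(t)   ⟹   Ctis(t) = K1 ∫₀ᵗ Cp(u) e^{−K2(t−u)} du,

where Cp(t) is the arterial input function and K1, K2 (min⁻¹) are the
clinically relevant rate constants. When no large vessel is in the field of
view (e.g. breast imaging), Cp cannot be measured directly and a population
template AIF biases the rates. This package instead estimates the AIF
*blindly* from the data, by maximum-entropy (ME) density fitting: among all
densities satisfying moment constraints E[ϕₖ(X)] = μₖ computed from the
plasma curve, take the one with maximal Shannon entropy,

    f(x) = exp(−Σₖ λₖ ϕₖ(x)),

with multipliers λ solved from the nonlinear moment equations by a
teaching-learning-based optimizer (TLBO) — a two-phase population method
that needs no starting point — or by a damped-Newton dual method as an
independent cross-check. With the constraint set {1, log x, x³} the fitted
family contains the Weibull density exp(log(k c⁻ᵏ) + (k−1)log x − (x/c)ᵏ),
so fitted multipliers translate directly into Weibull bolus parameters.
Rate constants are then estimated from the linearized (cumulative-integral)
form of the kinetic model by Bayesian MAP with a Gaussian likelihood and a
maximum-entropy prior, with plain linear least squares as the comparator.

The package also ships five classical Weibull estimators (empirical, method
of moments, MLE, binned MMLE, CDF least squares) for comparison, the
goodness metrics used to rank fitted AIF models (KL divergence, MAE, RMSE,
reduced χ², R², adjusted R², differential entropy), and a synthetic study
generator (46 frames every 11.9 s, per-patient ground-truth rates) so the
whole pipeline is testable without patient data.

## Worked example

The exact mapping between Weibull parameters and ME multipliers, plus a
round trip through moment fitting on a synthetic plasma sample:

```sh
$ dcemaxent reproduce-example
Weibull(k=3, c=1.8498) maximum-entropy multipliers:
  lambda0 = 0.7466
  lambda1 = -2.0000
  lambda2 = 0.1580
moments of a 2000-draw synthetic plasma sample: E[log x] = 0.4163, E[x^3] = 6.3204
refit multipliers: lambda = [0.7383, -1.9196, 0.154] (max moment residual 1.31e-07)
```

The first block is the algebraic map λ0 = −log(k c⁻ᵏ), λ1 = −(k−1),
λ2 = c⁻ᵏ for a Weibull bolus with shape 3 and scale 1.8498 min. The second
block draws 2000 concentrations from that Weibull, computes the sample
moments of log x and x³, and re-solves the ME problem with TLBO: the
recovered multipliers agree with the algebraic ones to within sampling
error, and the moment equations are satisfied to ~1e-7.

Kinetic fitting on a simulated study (46 frames at 11.9 s, noise sd = 5% of
tissue peak):

```python
from dcemaxent import StudyConfig, simulate_study, murase_design_matrix, map_fit

for r in simulate_study(StudyConfig(n_patients=3, seed=1)):
    fit = map_fit(murase_design_matrix(r.cp, r.ctis), r.ctis.values)
    print(f"{r.patient_id}: K1 = {fit.params.k1:.4f} (true {r.truth.k1:.4f}), "
          f"K2 = {fit.params.k2:.4f} (true {r.truth.k2:.4f})")
```

```
patient_01: K1 = 0.6090 (true 0.6118), K2 = 0.3828 (true 0.3807)
patient_02: K1 = 0.2404 (true 0.2442), K2 = 0.3775 (true 0.3800)
patient_03: K1 = 0.4156 (true 0.4118), K2 = 0.1814 (true 0.1751)
```

The full pipeline (simulate → fit-aif → fit-kinetics → evaluate) runs as
`dcemaxent run --n-patients 12 --seed 0 --out-dir run/` and writes
`curves.csv`, per-patient density JSONs, a 12-row `kinetics.csv` table and
`metrics.csv`, each stamped with the seed and config hash; identical seeds
give byte-identical reports. See `dcemaxent --help` for the individual
subcommands, and `docs/methods.md` for models, defaults and numerical
choices.

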