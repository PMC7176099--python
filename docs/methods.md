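# Methods

## Model and assumptions

All modelling happens on the Fisher-z scale, θ̂ = atanh(r), where a
correlation estimate from n observations is treated as exactly normal with
known variance σ² = 1/(n − 3). This is an asymptotic approximation; it is
the reason sample sizes below ~10 should be viewed with suspicion (the
package warns below n = 4 and refuses n ≤ 3). Sample sizes may be
non-integer "effective" sizes. The hierarchical model

    θ̂ₖ | θₖ ~ N(θₖ, σₖ²),  θₖ | θ ~ N(θ, τ²),  θ ~ prior,  k ∈ {o, r}

treats the heterogeneity variance τ² as fixed and known, which is what
keeps every predictive distribution normal and closed-form. τ cannot be
estimated from a single original study (θ and τ² are confounded in the
marginal likelihood), hence the fixed default below. No priors are placed
on variance components; the empirical-Bayes g is a plug-in, so the reported
predictive variances ignore the uncertainty in g and τ.

Two priors for θ are supported. The flat prior yields
θ̂ᵣ | θ̂ₒ ~ N(θ̂ₒ, σₒ² + σᵣ² + 2τ²). The sceptical prior is the zero-mean
g-prior N(0, g·(σₒ² + τ²)) with g fixed at its marginal-likelihood maximum
ĝ = max{tₒ²/(1 + d) − 1, 0}, giving the shrinkage factor
s = ĝ/(1 + ĝ) = max{1 − (1 + d)/tₒ², 0} and
θ̂ᵣ | θ̂ₒ ~ N(s·θ̂ₒ, s·(σₒ² + τ²) + σᵣ² + τ²). On the test-statistic scale
both predictives depend only on (tₒ, c, d) with c = σₒ²/σᵣ² and
d = τ²/σₒ²; the t-scale forms are exactly the z-scale forms divided by σᵣ
(the mean carries a factor √c, which follows from dimensional analysis and
is enforced by a scale-consistency test). The general conjugate prior with
free mean and variance is deliberately out of scope.

## Parameters that matter

* **τ (heterogeneity SD, Fisher-z units; default 0.08).** Chosen via the
  δ(τ) device: δ(τ) = tanh(z₀.₀₂₅·τ) − tanh(−z₀.₀₂₅·τ) is the
  correlation-scale width of the central 95% range of study-specific
  effects at an overall effect of zero. τ = 0.08 gives δ ≈ 0.311, about
  the width of a medium correlation effect (Cohen r = 0.3) — small, as
  direct replications are matched closely to their originals. δ(0.08)
  slightly exceeds 0.3; the exact value is reported rather than forcing
  δ ≤ 0.3. `tau_for_delta` inverts δ by Brent root-finding (xtol 1e-10);
  at θ = 0 the closed form atanh(δ/2)/z₀.₀₂₅ serves as the test oracle.
  θ = 0 is the default anchor; a general-θ variant exists but is unused by
  the defaults.
* **α (significance level, default 0.05 two-sided)** defines both the
  observed binary outcome and the forecast probability of "significant
  replication".
* **level (prediction-interval level, default 0.95).**

## Conventions

* **Orientation.** Every analysis first flips pairs so the original
  correlation is non-negative (both estimates negated); "same direction"
  is defined relative to the oriented original. An exactly zero original
  is left as is; its sceptical forecast degenerates to mean zero, which is
  valid, while the design functions (`replication_probability`,
  `required_replication_n`) require tₒ > 0. The evaluation report records
  how many pairs were flipped.
* **Significance of a replication** means two-sided p < α *and* the same
  sign as the oriented original. The forecast probability is accordingly
  the one-tailed P(t_r > z_{α/2}); a `two_sided` flag adds the (normally
  negligible) opposite tail to both the outcome definition and the
  forecast.
* All scoring happens on the Fisher-z scale; the correlation scale is
  presentation-only (interval endpoints through tanh, a monotone map that
  preserves coverage).

## Scoring and calibration machinery

LS is the negative log predictive density, QS the density formulation
−2f(y) + ∫f², CRPS the standard normal closed form; all negatively
oriented, no truncation of extreme values. For binary forecasts, the mean
Brier score and its skill normalization against the outcome base rate.

The four score-based calibration tests exploit null moments available in
closed form: under calibration LS_i = log(2π v_i)/2 + Z²/2 with Z standard
normal, so E[LS_i] is known and Var[LS_i] = 1/2; CRPS_i = √v_i·C(Z) with
E[C] = 1/√π and Var[C] = κ. The constant κ ≈ 0.16275 is not tabulated
anywhere convenient; it is computed once per session by adaptive quadrature
of E[C²] − 1/π and validated in the tests against a large Monte Carlo
sample. Tests (i)/(ii) are unconditional z-tests of the standardized score
sums. Tests (iii)/(iv) regress the individual scores on a transform of the
predictive spread — LS on log √v_i (null intercept log(2π)/2 + 1/2, slope
1), CRPS on √v_i through a 1/v_i-weighted fit (null intercept 0, slope
1/√π) — and test the null coefficient pair by a joint Wald χ²(2) using the
known null residual variances (1/2 and κ) rather than estimated ones. The
exact transforms and intercept handling were open design choices; the
binding requirement, verified by simulation in the acceptance suite, is
nominal type-I error (all four tests sit at ~0.044–0.048 at n = 73) with
high power against variance misspecification. Both regression tests are
flagged not-applicable when the predictive variances are constant. The
four p-values are summarized by their plain harmonic mean (no recalibration),
with underflowed p-values floored at 1e-300 so the summary stays defined.

Other diagnostics: the KS uniformity test of the PIT values uses the exact
small-sample null distribution up to n = 100 and the asymptotic one beyond;
the calibration slope is a statsmodels logistic regression of the outcomes
on logit(p), with probabilities at 0/1 clipped to ±1e-6 and complete
separation reported as `not_estimable` rather than an error; the AUC is the
tie-corrected Mann-Whitney statistic with a Hanley–McNeil standard error,
interval built on the logit scale and back-transformed, and no interval at
AUC 0 or 1; the observed-vs-expected comparison is a two-cell χ²(1) without
continuity correction, where the expected count is the sum of the forecast
probabilities; paired score comparisons use a paired t-test by default with
a seeded sign-flip permutation alternative.

## Design tools

`replication_probability` is the predictive tail mass beyond z_{α/2};
it is monotone increasing in the replication sample size (provable from
the t-scale form), so `required_replication_n` checks attainability
against the analytic c → ∞ power limit — Φ(tₒ/√(1 + 2d)) for the flat
prior, Φ(s·tₒ/√(s(1 + d) + d)) for the sceptical one — and then brackets
and bisects on integers, returning a NOT_ATTAINABLE sentinel when the
target exceeds the limit (in particular whenever s = 0 and the target
exceeds the trivial α/2 or ½ bound).

## Synthetic projects

The generator draws each pair from the hierarchical model itself
(θ ~ N(effect_mean, effect_sd²); study effects around θ with SD τ;
estimates with variance 1/(n − 3)) and reports correlations by tanh.
Defaults: 73 pairs, effect_mean 0.2 and effect_sd 0.15 on the Fisher-z
scale (small-to-medium correlations, the typical range in social-science
replication projects), τ = 0.08 matching the analysis default, original
sample sizes uniform on {20, …, 100} (covering variance ratios of roughly
one half to two when replications are equal-sized, the practically relevant
band), equal-sized replications. With `selection` on, the whole triple
(θ, θ_o, θ̂_o) is redrawn until the original is two-sided significant at
`selection_alpha` — file-drawer selection of *studies*, not truncation of
a single estimate — and the replication is drawn afterwards,
unconditionally. This emulates publication-bias inflation of the published
originals; it does not model p-hacking or other questionable research
practices, nor many-to-one replication designs. One `numpy` generator
instance is seeded per simulation; there is no global random state, and
evaluation itself is fully deterministic.

What passing the synthetic self-consistency suite shows — and what it does
not: data drawn from a method's own predictive distribution must yield
nominal interval coverage, uniform PIT values and nominal type-I error of
every calibration test, and the suite verifies exactly that, plus recovery
of the generating τ by mean-score minimization and the qualitative
inflation pattern under selection (shrinkage methods score better, the
naive expected significant count overshoots the observed one). Real
replication data can violate the model in ways the generator never
produces — non-normal effects, correlated study selection, τ varying by
pair — so passing here demonstrates internal correctness of the machinery,
not that any particular field's data satisfy the model.

## Problem sizes and numerical choices in the test suite

The simulation experiments use sizes chosen to make the Monte Carlo noise
small relative to the tested tolerances: 10⁴ pairs for interval coverage
(binomial SE ≈ 0.002 against a ±0.01 band), 1000 replicates of 73-pair
projects for test-size checks (±3 binomial SEs), 500 pairs for τ recovery
on a 0.01 grid (the mean-CRPS curve is shallow, so one grid step of slack
is allowed), and 100 projects of 50 pairs for the selection ordering.
Fixed seeds make every stochastic test reproducible.

## Known limitations

Known τ² and plug-in ĝ understate predictive uncertainty; the normal
likelihood is questionable for very small n; only correlation effect sizes
are supported end to end (the framework itself would cover any effect
measure with a normalizing transform); the harmonic-mean summary of
dependent p-values is descriptive, not a calibrated test at a fixed level;
and the evaluation assumes one replication per original study.
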