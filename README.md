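# repforecast

Probabilistic forecasting and evaluation of replication study outcomes.

Large-scale replication projects (psychology, experimental economics, social
sciences, experimental philosophy) rerun published studies and ask whether
the original findings hold up. `repforecast` answers the quantitative
version of that question: *given only the original effect estimate and the
two sample sizes, what should we expect the replication estimate to be* —
and, once the replication is run, *how good were those forecasts?* It is
aimed at meta-researchers evaluating replication projects and at teams
designing replication studies (prediction intervals, replication
probability, sample size).

## Model

Effect estimates are correlations, moved to the Fisher-z scale
θ̂ = atanh(r), where they are approximately normal with variance
1/(n − 3). The hierarchical model is

```
θ̂ₖ | θₖ ~ N(θₖ, σₖ²)       k ∈ {o, r}   (sampling error)
θₖ  | θ  ~ N(θ,  τ²)                     (between-study heterogeneity)
θ        ~ prior                         (overall effect)
```

Two priors give closed-form normal predictive distributions of the
replication estimate θ̂ᵣ given the original θ̂ₒ:

* **flat prior** — θ̂ᵣ | θ̂ₒ ~ N(θ̂ₒ, σₒ² + σᵣ² + 2τ²). With τ = 0 this is
  the naive model behind the familiar replication prediction intervals.
* **sceptical prior** — a zero-mean g-prior N(0, g·(σₒ² + τ²)) with g set
  by empirical Bayes, which shrinks the original estimate by
  s = max{1 − (1 + d)/tₒ², 0} (tₒ = θ̂ₒ/σₒ, d = τ²/σₒ²):
  θ̂ᵣ | θ̂ₒ ~ N(s·θ̂ₒ, s·(σₒ² + τ²) + σᵣ² + τ²). Weak originals are shrunk
  hard (*evidence-based shrinkage*), counteracting regression to the mean
  and publication-bias inflation.

The four canonical methods are N (flat, τ=0), S (sceptical, τ=0), H (flat,
τ=0.08) and SH (sceptical, τ=0.08); the default τ = 0.08 corresponds to a
95% range of study-specific effects about the width of a medium correlation
effect (see `repforecast.heterogeneity`).

The evaluation toolbox covers discrimination, calibration and sharpness of
the forecasts: logarithmic, quadratic and continuous ranked probability
scores, four score-based calibration tests summarized by a harmonic-mean p,
PIT histograms with a KS uniformity test, prediction-interval coverage and —
for the induced binary forecasts of a *significant same-direction
replication* — Brier and normalized Brier scores, Spiegelhalter's z,
observed-vs-expected χ², logistic calibration slope and AUC. A synthetic
generator simulates whole replication projects from the hierarchical model,
optionally with significance selection of the originals (publication bias).

## Worked example

An original study reports r = 0.45 with n = 32; a replication with n = 65
is planned.

```python
from repforecast import *
from repforecast.models import MethodSpec

z = ZEstimate.from_correlation(0.45, 32)        # theta=0.4847, var=0.03448, t_o=2.610
naive = flat_predictive(z, z_variance(65), tau=0.0)
shrunk = sceptical_predictive(z, z_variance(65), tau=0.08)

prediction_interval(naive, 0.95, "correlation")   # (0.044, 0.729)
prediction_interval(shrunk, 0.95, "correlation")  # (-0.065, 0.699)

c = variance_ratio(32, 65)                        # 2.138
d = relative_heterogeneity(0.08, 32)              # 0.1856
replication_probability(z.t, c, 0.0, prior="flat")        # 0.853
replication_probability(z.t, c, d, prior="sceptical")     # 0.738

required_replication_n(z.t, 32, 0.8, method=MethodSpec("sceptical", 0.08))  # 91
```

The naive 95% prediction interval excludes zero, the sceptical one does
not: after evidence-based shrinkage (s ≈ 0.83) the forecast mean drops from
r ≈ 0.45 to r ≈ 0.38, the chance of a significant same-direction
replication falls from 85% to 74%, and reaching 80% power under the
SH method needs 91 participants rather than 57 under H.

Evaluating a whole project from the shell:

```
repforecast simulate --n-pairs 73 --selection --seed 1 --out pairs.csv
repforecast evaluate --input pairs.csv --tau 0.08 --out report.json
repforecast ssize --to 2.8 --no 53 --power 0.8 --method H
```

`evaluate` writes a JSON report with, per method, the mean scores, the
calibration-test p-values, PI coverage, PIT values, expected vs observed
significant counts, Brier scores, calibration slope and AUC. Input CSVs use
the schema `study,ro,no,rr,nr,pm_belief` (one row per original/replication
pair; `pm_belief` optionally carries prediction-market probabilities, which
are evaluated with the binary-forecast metrics alongside the statistical
methods).

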