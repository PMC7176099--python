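"""Calibration and discrimination diagnostics for replication forecasts.

Under perfect calibration the observations are indistinguishable from draws
of their own predictive distributions, which pins down the distribution of
the proper scores and of the probability integral transform (PIT).  This
module implements the resulting tests:

* Spiegelhalter's z-test for binary probability forecasts;
* four score-based tests for normal predictives (unconditional z-tests on
  the mean LS and mean CRPS, whose null moments are available in closed
  form, plus two regression tests in which the individual scores are
  regressed on a transform of their predictive spread and the analytically
  known null intercept/slope are tested jointly), summarized by the
  harmonic mean of their p-values;
* PIT values with a Kolmogorov-Smirnov uniformity test;
* a logistic calibration slope (1 under calibration) and the Mann-Whitney
  AUC for discrimination of binary forecasts;
* a two-cell chi-square test comparing the observed with the expected
  number of significant replications, and paired tests for score
  differences between competing forecasters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, stats

from .models import NormalPredictive
from .scoring import BinaryForecastSet, crps, log_score

__all__ = [
    "CalibrationTestResult",
    "SlopeResult",
    "AucResult",
    "spiegelhalter_z",
    "crps_variance_kappa",
    "score_calibration_tests",
    "harmonic_mean_p",
    "pit",
    "ks_uniform",
    "calibration_slope",
    "auc",
    "expected_significant",
    "chisq_gof",
    "compare_scores_paired",
]


@dataclass(frozen=True)
class CalibrationTestResult:
    test_name: str
    statistic: float
    p_value: float
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status == "ok" and not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class SlopeResult:
    """Logistic calibration slope with Wald 95% CI; 1 under calibration."""

    slope: float
    ci: tuple[float, float] | None
    status: str = "ok"


@dataclass(frozen=True)
class AucResult:
    """Mann-Whitney AUC with logit-scale Wald 95% CI (none at AUC 0 or 1)."""

    auc: float
    ci: tuple[float, float] | None


def spiegelhalter_z(f: BinaryForecastSet) -> CalibrationTestResult:
    """Spiegelhalter's z-test for calibration of binary probability forecasts."""
    p, o = f.probabilities, f.outcomes
    num = float(np.sum((o - p) * (1.0 - 2.0 * p)))
    den2 = float(np.sum((1.0 - 2.0 * p) ** 2 * p * (1.0 - p)))
    if den2 <= 0:
        raise ValueError(
            "Spiegelhalter's z is undefined: zero variance (all forecasts 0.5, 0, or 1)"
        )
    z = num / math.sqrt(den2)
    return CalibrationTestResult("spiegelhalter_z", z, 2.0 * stats.norm.sf(abs(z)))


@lru_cache(maxsize=1)
def crps_variance_kappa() -> float:
    """Variance of the CRPS of a standard normal forecast at a N(0,1) draw.

    Universal constant kappa with Var[CRPS] = kappa * v for a calibrated
    normal forecast with variance v; computed once by adaptive quadrature
    (the mean is 1/sqrt(pi)).
    """

    def c(z):
        return z * (2.0 * stats.norm.cdf(z) - 1.0) + 2.0 * stats.norm.pdf(z) - 1.0 / np.sqrt(np.pi)

    second, _ = integrate.quad(lambda z: c(z) ** 2 * stats.norm.pdf(z), -np.inf, np.inf)
    return second - 1.0 / np.pi


def _score_arrays(preds, ys):
    from .scoring import _batch

    pred = _batch(preds)
    mu = np.atleast_1d(np.asarray(pred.mean, dtype=float))
    v = np.broadcast_to(np.asarray(pred.variance, dtype=float), mu.shape).astype(float)
    y = np.atleast_1d(np.asarray(ys, dtype=float))
    if y.shape != mu.shape:
        raise ValueError("forecasts and observations must have equal length")
    return NormalPredictive(mean=mu, variance=v, scale=pred.scale), mu, v, y


def score_calibration_tests(preds, ys) -> dict[str, CalibrationTestResult]:
    """The four score-based calibration tests for normal predictives.

    Unconditional tests: under calibration ``E[LS_i] = log(2 pi v_i)/2 + 1/2``
    with ``Var[LS_i] = 1/2`` (the LS is a shifted chi-square), and
    ``E[CRPS_i] = sqrt(v_i / pi)`` with ``Var[CRPS_i] = kappa v_i``; the
    standardized sums are compared with N(0, 1).

    Regression tests: the individual LS is regressed on ``log sqrt(v_i)``
    (null intercept ``log(2 pi)/2 + 1/2``, slope 1, residual variance 1/2)
    and the individual CRPS on ``sqrt(v_i)`` through a weighted fit with
    weights ``1/v_i`` (null intercept 0, slope ``1/sqrt(pi)``, standardized
    residual variance kappa).  Calibration is tested by a joint Wald
    chi-square with 2 degrees of freedom using the known null variances.
    Both regression tests are flagged not-applicable when the predictive
    variances are (numerically) constant.
    """
    pred, mu, v, y = _score_arrays(preds, ys)
    n = y.size
    if n < 3:
        raise ValueError("score-based calibration tests need at least 3 forecasts")
    ls = log_score(pred, y)
    cr = crps(pred, y)
    kappa = crps_variance_kappa()
    results: dict[str, CalibrationTestResult] = {}

    z_ls = float(np.sum(ls - (0.5 * np.log(2.0 * np.pi * v) + 0.5)) / math.sqrt(0.5 * n))
    results["ls_unconditional"] = CalibrationTestResult(
        "ls_unconditional", z_ls, 2.0 * stats.norm.sf(abs(z_ls))
    )
    z_cr = float(np.sum(cr - np.sqrt(v / np.pi)) / math.sqrt(kappa * np.sum(v)))
    results["crps_unconditional"] = CalibrationTestResult(
        "crps_unconditional", z_cr, 2.0 * stats.norm.sf(abs(z_cr))
    )

    if np.ptp(np.log(v)) < 1e-10:
        for name in ("ls_regression", "crps_regression"):
            results[name] = CalibrationTestResult(name, math.nan, math.nan, status="not_applicable")
        return results

    # LS on log sqrt(v): homoscedastic with known null residual variance 1/2.
    x = 0.5 * np.log(v)
    X = np.column_stack([np.ones(n), x])
    beta0 = np.array([0.5 * math.log(2.0 * math.pi) + 0.5, 1.0])
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ ls)
    t_ls = float((beta - beta0) @ xtx @ (beta - beta0) / 0.5)
    results["ls_regression"] = CalibrationTestResult(
        "ls_regression", t_ls, float(stats.chi2.sf(t_ls, 2))
    )

    # CRPS on sqrt(v): heteroscedastic, weights 1/v, known null variance kappa.
    Xc = np.column_stack([np.ones(n), np.sqrt(v)])
    beta0c = np.array([0.0, 1.0 / math.sqrt(math.pi)])
    w = 1.0 / v
    xtwx = Xc.T @ (w[:, None] * Xc)
    betac = np.linalg.solve(xtwx, Xc.T @ (w * cr))
    t_cr = float((betac - beta0c) @ xtwx @ (betac - beta0c) / kappa)
    results["crps_regression"] = CalibrationTestResult(
        "crps_regression", t_cr, float(stats.chi2.sf(t_cr, 2))
    )
    return results


def harmonic_mean_p(ps) -> float:
    """Harmonic mean of p-values, a summary lying between their min and max."""
    p = np.atleast_1d(np.asarray(ps, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(p.size / np.sum(1.0 / p))


def pit(pred: NormalPredictive, y):
    """Probability integral transform: predictive CDF at the observed value."""
    out = pred.cdf(y)
    return out.item() if np.ndim(out) == 0 else out


def ks_uniform(pits) -> CalibrationTestResult:
    """One-sample Kolmogorov-Smirnov test of PIT values against Uniform(0, 1).

    Uses the exact small-sample null distribution up to n = 100 and the
    asymptotic one beyond.
    """
    u = np.atleast_1d(np.asarray(pits, dtype=float))
    if u.size == 0:
        raise ValueError("empty PIT list")
    if np.any((u < 0) | (u > 1)):
        raise ValueError("PIT values must lie in [0, 1]")
    method = "exact" if u.size <= 100 else "asymp"
    res = stats.kstest(u, "uniform", method=method)
    return CalibrationTestResult("ks_uniform", float(res.statistic), float(res.pvalue))


_CLIP_EPS = 1e-6


def calibration_slope(f: BinaryForecastSet) -> SlopeResult:
    """Logistic regression of the outcomes on the logit of the forecasts.

    Slope 1 indicates calibration.  Forecasts at exactly 0 or 1 are clipped
    to [1e-6, 1 - 1e-6] with a warning; complete separation of the outcome
    classes makes the slope non-estimable.
    """
    import statsmodels.api as sm

    p, o = f.probabilities, f.outcomes
    if o.min() == o.max():
        raise ValueError("calibration slope requires both outcome classes")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("forecast probabilities at 0 or 1 clipped for the logit transform")
        p = np.clip(p, _CLIP_EPS, 1.0 - _CLIP_EPS)
    x = np.log(p / (1.0 - p))
    if np.ptp(x) < 1e-12:
        raise ValueError("calibration slope requires variation in the forecasts")
    if x[o == 1].min() > x[o == 0].max() or x[o == 1].max() < x[o == 0].min():
        return SlopeResult(math.nan, None, status="not_estimable")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(o, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            return SlopeResult(math.nan, None, status="not_estimable")
    except Exception:
        return SlopeResult(math.nan, None, status="not_estimable")
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if not math.isfinite(se) or se > 1e3:
        return SlopeResult(slope, None, status="not_estimable")
    q = stats.norm.ppf(0.975)
    return SlopeResult(slope, (slope - q * se, slope + q * se))


def auc(f: BinaryForecastSet) -> AucResult:
    """Mann-Whitney AUC with tie correction and a logit-scale Wald 95% CI.

    The standard error follows Hanley & McNeil; at AUC exactly 0 or 1 the
    point value is returned without an interval.
    """
    p, o = f.probabilities, f.outcomes
    n1 = int(o.sum())
    n0 = o.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = stats.rankdata(p)
    a = (ranks[o == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    a = float(a)
    if a in (0.0, 1.0):
        return AucResult(a, None)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n0 * n1)
    se_logit = math.sqrt(var) / (a * (1.0 - a))
    z = stats.norm.ppf(0.975)
    lo = math.log(a / (1 - a)) - z * se_logit
    hi = math.log(a / (1 - a)) + z * se_logit
    expit = lambda t: 1.0 / (1.0 + math.exp(-t))
    return AucResult(a, (expit(lo), expit(hi)))


def expected_significant(probs) -> float:
    """Expected number of significant replications: the sum of the forecasts."""
    p = np.atleast_1d(np.asarray(probs, dtype=float))
    if p.size == 0:
        raise ValueError("empty probability list")
    return float(p.sum())


def chisq_gof(observed: float, expected: float, n: int) -> CalibrationTestResult:
    """Two-cell chi-square test of an observed vs expected significant count.

    ``X^2 = (O - E)^2/E + (O - E)^2/(n - E)`` on 1 degree of freedom, no
    continuity correction.
    """
    if not 0 < expected < n:
        raise ValueError("expected count must lie strictly between 0 and n")
    if not 0 <= observed <= n:
        raise ValueError("observed count must lie in [0, n]")
    x2 = (observed - expected) ** 2 / expected + (observed - expected) ** 2 / (n - expected)
    return CalibrationTestResult("chisq_gof", float(x2), float(stats.chi2.sf(x2, 1)))


def compare_scores_paired(
    scores_a, scores_b, method: str = "t", n_permutations: int = 10**4, seed: int = 0
) -> CalibrationTestResult:
    """Two-sided paired test of equal predictive performance via score differences.

    Default is a paired t-test on the per-study differences; ``method=
    'permutation'`` runs a seeded sign-flip permutation test instead.
    """
    a = np.atleast_1d(np.asarray(scores_a, dtype=float))
    b = np.atleast_1d(np.asarray(scores_b, dtype=float))
    if a.shape != b.shape or a.size < 3:
        raise ValueError("score lists must have equal length >= 3")
    diff = a - b
    if np.ptp(diff) < 1e-14:
        if abs(float(diff.mean())) > 0:
            warnings.warn("constant non-zero score difference; p-value degenerate")
        return CalibrationTestResult("paired_" + method, float(diff.mean()), 1.0)
    if method == "t":
        res = stats.ttest_rel(a, b)
        return CalibrationTestResult("paired_t", float(res.statistic), float(res.pvalue))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        obs = abs(diff.mean())
        signs = rng.choice((-1.0, 1.0), size=(n_permutations, diff.size))
        perm = np.abs((signs * diff).mean(axis=1))
        p = (1.0 + np.sum(perm >= obs)) / (n_permutations + 1.0)
        return CalibrationTestResult("paired_permutation", float(obs), float(p))
    raise ValueError(f"unknown method {method!r}")
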