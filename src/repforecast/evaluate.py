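"""End-to-end evaluation of replication forecasts for one project.

:func:`evaluate_project` orients each study pair, builds the per-pair
predictive distribution of the replication estimate on the Fisher-z scale
for every requested method, and computes the full evaluation report: mean
proper scores with the harmonic-mean p of the four score-based calibration
tests, prediction-interval coverage, PIT values with a KS uniformity test,
and — for the induced binary forecasts of a significant same-direction
replication — observed vs expected counts with a chi-square test, (normalized)
Brier scores, Spiegelhalter's z, the logistic calibration slope and the AUC.
An optional prediction-market column is evaluated with the binary metrics
only.  All evaluation is deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import calibration as cal
from . import scoring
from .models import FISHER_Z, MethodSpec, NormalPredictive, prediction_interval, shrinkage_factor
from .transforms import StudyPair, fisher_z, orient_pair, z_variance

__all__ = ["EvaluationReport", "MethodResult", "evaluate_project", "coverage", "tau_sensitivity"]

logger = logging.getLogger("repforecast")

REPORT_VERSION = 1


def _project_arrays(pairs: list[StudyPair]):
    """Orient pairs and pull out the Fisher-z quantities as arrays."""
    oriented = [orient_pair(p) for p in pairs]
    missing = [p.study_id for p in oriented if not p.has_replication]
    if missing:
        raise ValueError(
            f"pairs without replication results: {missing}; evaluation needs observed "
            "replications (use the design tools for planned studies)"
        )
    theta_o = np.array([fisher_z(p.r_o) for p in oriented])
    v_o = np.array([z_variance(p.n_o) for p in oriented])
    v_r = np.array([z_variance(p.n_r) for p in oriented])
    y = np.array([fisher_z(p.r_r) for p in oriented])
    pm = np.array(
        [math.nan if p.pm_belief is None else p.pm_belief for p in oriented]
    )
    n_flipped = sum(1 for p, q in zip(pairs, oriented) if p is not q)
    return theta_o, v_o, v_r, y, pm, n_flipped


def method_predictive(theta_o, v_o, v_r, method: MethodSpec) -> NormalPredictive:
    """Batch Fisher-z-scale predictive distribution for one method."""
    theta_o = np.asarray(theta_o, dtype=float)
    v_o = np.asarray(v_o, dtype=float)
    v_r = np.asarray(v_r, dtype=float)
    tau2 = method.tau**2
    if method.prior == "flat":
        mean = theta_o
        var = v_o + v_r + 2.0 * tau2
    else:
        with np.errstate(invalid="ignore"):
            t_o = np.where(v_o > 0, theta_o / np.sqrt(v_o), 0.0)
        s = shrinkage_factor(t_o, tau2 / v_o)
        mean = s * theta_o
        var = s * (v_o + tau2) + v_r + tau2
    return NormalPredictive(mean=mean, variance=var, scale=FISHER_Z)


def significance_probability(theta_o, v_o, v_r, method: MethodSpec, alpha: float = 0.05,
                             two_sided: bool = False):
    """Forecast probability of a significant same-direction replication per pair.

    Computed on the Fisher-z scale as ``P(theta_hat_r > z_{alpha/2} sigma_r)``
    under the method's predictive; valid for oriented pairs including
    ``t_o = 0`` (where the sceptical forecast is mean zero).
    """
    pred = method_predictive(theta_o, v_o, v_r, method)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    thresh = z_crit * np.sqrt(np.asarray(v_r, dtype=float))
    p = stats.norm.sf(thresh, loc=pred.mean, scale=pred.sd)
    if two_sided:
        p = p + stats.norm.cdf(-thresh, loc=pred.mean, scale=pred.sd)
    return p


@dataclass(frozen=True)
class MethodResult:
    """Evaluation results of one forecasting method on one project."""

    label: str
    n: int
    mean_qs: float | None = None
    mean_ls: float | None = None
    mean_crps: float | None = None
    calibration_p: dict = field(default_factory=dict)
    harmonic_p: float | None = None
    pi_coverage: float | None = None
    pit_values: list = field(default_factory=list)
    ks_p: float | None = None
    significance_probs: list = field(default_factory=list)
    observed_significant: int | None = None
    expected_significant: float | None = None
    chisq_p: float | None = None
    bs: float | None = None
    bs_norm: float | None = None
    spiegelhalter_z: float | None = None
    spiegelhalter_p: float | None = None
    slope: float | None = None
    slope_ci: tuple | None = None
    slope_status: str = "ok"
    auc: float | None = None
    auc_ci: tuple | None = None


@dataclass(frozen=True)
class EvaluationReport:
    """Per-method results plus run metadata; mirrors the printed tables."""

    methods: dict
    n_pairs: int
    alpha: float
    level: float
    n_oriented: int
    report_version: int = REPORT_VERSION

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and not math.isfinite(x):
                return None
            if isinstance(x, (np.floating, np.integer)):
                return clean(x.item())
            if isinstance(x, tuple):
                return [clean(v) for v in x]
            if isinstance(x, list):
                return [clean(v) for v in x]
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            return x

        return clean(
            {
                "report_version": self.report_version,
                "n_pairs": self.n_pairs,
                "alpha": self.alpha,
                "level": self.level,
                "n_oriented": self.n_oriented,
                "methods": {
                    label: dataclasses.asdict(res) for label, res in self.methods.items()
                },
            }
        )


def _binary_metrics(probs: np.ndarray, outcomes: np.ndarray) -> dict:
    f = scoring.BinaryForecastSet(probs, outcomes)
    out: dict = {"bs": scoring.brier(f)}
    mixed = 0 < outcomes.mean() < 1
    out["bs_norm"] = scoring.brier_normalized(f) if mixed else None
    try:
        sp = cal.spiegelhalter_z(f)
        out["spiegelhalter_z"] = sp.statistic
        out["spiegelhalter_p"] = sp.p_value
    except ValueError:
        out["spiegelhalter_z"] = out["spiegelhalter_p"] = None
    if mixed:
        sl = cal.calibration_slope(f)
        out["slope"], out["slope_ci"], out["slope_status"] = sl.slope, sl.ci, sl.status
        a = cal.auc(f)
        out["auc"], out["auc_ci"] = a.auc, a.ci
    else:
        out["slope"] = out["slope_ci"] = out["auc"] = out["auc_ci"] = None
        out["slope_status"] = "not_estimable"
    n = outcomes.size
    observed = int(outcomes.sum())
    expected = cal.expected_significant(probs)
    out["observed_significant"] = observed
    out["expected_significant"] = expected
    if 0 < expected < n:
        out["chisq_p"] = cal.chisq_gof(observed, expected, n).p_value
    else:
        out["chisq_p"] = None
    return out


def evaluate_project(
    pairs: list[StudyPair],
    methods=None,
    alpha: float = 0.05,
    level: float = 0.95,
    two_sided: bool = False,
) -> EvaluationReport:
    """Evaluate forecasting methods on a project of observed replications."""
    from .models import DEFAULT_METHODS

    if methods is None:
        methods = DEFAULT_METHODS
    if len(pairs) < 2:
        raise ValueError("evaluation needs at least 2 study pairs")
    theta_o, v_o, v_r, y, pm, n_flipped = _project_arrays(pairs)
    n = y.size
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    t_r = y / np.sqrt(v_r)
    outcomes = (np.abs(t_r) > z_crit) & (t_r > 0) if not two_sided else (np.abs(t_r) > z_crit)
    outcomes = outcomes.astype(float)

    results: dict[str, MethodResult] = {}
    for method in methods:
        pred = method_predictive(theta_o, v_o, v_r, method)
        ms = scoring.mean_scores(pred, y)
        if n >= 3:
            tests = cal.score_calibration_tests(pred, y)
        else:  # too few pairs for any score-based test; report NA
            tests = {}
        # floor underflowed p-values so the harmonic mean stays defined
        usable = [max(t.p_value, 1e-300) for t in tests.values() if t.status == "ok"]
        harmonic = cal.harmonic_mean_p(usable) if tests and len(usable) == len(tests) else None
        lower, upper = prediction_interval(pred, level)
        cov = float(np.mean((y >= lower) & (y <= upper)))
        pits = cal.pit(pred, y)
        ks = cal.ks_uniform(pits)
        probs = significance_probability(theta_o, v_o, v_r, method, alpha, two_sided)
        binary = _binary_metrics(probs, outcomes)
        results[method.label] = MethodResult(
            label=method.label,
            n=n,
            mean_qs=ms["qs"],
            mean_ls=ms["ls"],
            mean_crps=ms["crps"],
            calibration_p={k: t.p_value for k, t in tests.items() if t.status == "ok"},
            harmonic_p=harmonic,
            pi_coverage=cov,
            pit_values=[float(u) for u in pits],
            ks_p=ks.p_value,
            significance_probs=[float(p) for p in probs],
            **binary,
        )
        logger.info(
            "method %s: n=%d tau=%g mean CRPS %.4f coverage %.3f",
            method.label, n, method.tau, ms["crps"], cov,
        )

    if np.all(np.isfinite(pm)):
        binary = _binary_metrics(pm, outcomes)
        results["PM"] = MethodResult(
            label="PM", n=n, significance_probs=[float(p) for p in pm], **binary
        )
    elif np.any(np.isfinite(pm)):
        logger.warning("pm_belief present for only some pairs; prediction-market metrics skipped")

    return EvaluationReport(
        methods=results, n_pairs=n, alpha=alpha, level=level, n_oriented=n_flipped
    )


def coverage(pairs: list[StudyPair], method: MethodSpec, level: float = 0.95) -> float:
    """Fraction of replication estimates inside their central prediction interval."""
    theta_o, v_o, v_r, y, _, _ = _project_arrays(pairs)
    pred = method_predictive(theta_o, v_o, v_r, method)
    lower, upper = prediction_interval(pred, level)
    return float(np.mean((y >= lower) & (y <= upper)))


def tau_sensitivity(pairs: list[StudyPair], priors=("flat", "sceptical"), tau_grid=None):
    """Mean scores as a function of the heterogeneity tau, per prior.

    Returns a dict with a tidy table of mean QS/LS/CRPS per (prior, tau) and
    the score-minimizing tau per prior and score type.
    """
    import pandas as pd

    if tau_grid is None:
        tau_grid = np.round(np.arange(0.0, 0.301, 0.01), 10)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau grid must be non-empty")
    if np.any(tau_grid < 0):
        raise ValueError("tau grid values must be non-negative")
    theta_o, v_o, v_r, y, _, _ = _project_arrays(pairs)
    rows = []
    for prior in priors:
        for tau in tau_grid:
            ms = scoring.mean_scores(
                method_predictive(theta_o, v_o, v_r, MethodSpec(prior, float(tau))), y
            )
            rows.append({"prior": prior, "tau": float(tau), **ms})
    table = pd.DataFrame(rows)
    argmin = {
        prior: {
            score: float(sub.loc[sub[score].idxmin(), "tau"])
            for score in ("qs", "ls", "crps")
        }
        for prior, sub in table.groupby("prior")
    }
    return {"table": table, "argmin": argmin}
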