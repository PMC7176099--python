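"""Predictive distributions of the replication effect estimate.

The underlying hierarchical normal model on the Fisher-z scale is

    theta_hat_k | theta_k ~ N(theta_k, sigma_k^2),   k in {o, r}
    theta_k     | theta   ~ N(theta,   tau^2)
    theta                 ~ prior

with fixed sampling variances ``sigma_k^2 = 1/(n_k - 3)`` and fixed
between-study heterogeneity ``tau^2``.  Two priors for the overall effect
``theta`` are supported, both giving closed-form normal predictive
distributions of the replication estimate given the original estimate:

* **flat** prior: the predictive is ``N(theta_hat_o,
  sigma_o^2 + sigma_r^2 + 2 tau^2)``; with ``tau = 0`` this is the naive
  model previously used to build replication prediction intervals.
* **sceptical** prior: a zero-mean normal prior with g-prior style variance
  ``g (sigma_o^2 + tau^2)``, with ``g`` set by empirical Bayes,
  ``g_hat = max(t_o^2/(1 + d) - 1, 0)``.  The original estimate is then
  shrunk by ``s = g_hat / (1 + g_hat) = max(1 - (1 + d)/t_o^2, 0)`` and the
  predictive is ``N(s theta_hat_o, s (sigma_o^2 + tau^2) + sigma_r^2 +
  tau^2)``.  Shrinkage is *evidence based*: weak originals (small ``t_o``)
  are shrunk hard, and ``s -> 1`` as ``t_o -> infinity``.

On the scale of the replication test statistic ``t_r = theta_hat_r/sigma_r``
the predictives depend on the data only through the original test statistic
``t_o``, the variance ratio ``c`` and the relative heterogeneity ``d``, which
is convenient for design (replication probability, sample size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .heterogeneity import TAU_DEFAULT
from .transforms import ZEstimate, inverse_fisher_z, relative_heterogeneity, variance_ratio, z_variance

__all__ = [
    "NormalPredictive",
    "MethodSpec",
    "ShrinkageResult",
    "NOT_ATTAINABLE",
    "DEFAULT_METHODS",
    "flat_predictive",
    "g_hat",
    "shrinkage_factor",
    "sceptical_predictive",
    "predictive_t",
    "prediction_interval",
    "replication_probability",
    "required_replication_n",
]

FISHER_Z = "fisher_z"
TEST_STATISTIC = "test_statistic"


class _NotAttainable:
    """Sentinel returned by sample-size planning when no n_r reaches the target."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NOT_ATTAINABLE"

    def __bool__(self) -> bool:
        return False


NOT_ATTAINABLE = _NotAttainable()


@dataclass(frozen=True)
class NormalPredictive:
    """A normal predictive distribution tagged with the scale it lives on.

    ``mean`` and ``variance`` may be scalars or equal-shaped arrays (a batch
    of per-study forecasts); all scoring and calibration code broadcasts.
    """

    mean: float | np.ndarray
    variance: float | np.ndarray
    scale: str = FISHER_Z

    def __post_init__(self) -> None:
        if self.scale not in (FISHER_Z, TEST_STATISTIC):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.all(np.asarray(self.variance) > 0):
            raise ValueError("predictive variance must be positive")

    @property
    def sd(self):
        return np.sqrt(self.variance)

    def cdf(self, y):
        return stats.norm.cdf(y, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class MethodSpec:
    """A forecasting method: a prior (flat/sceptical) plus a heterogeneity tau.

    Canonical labels: N = (flat, 0), S = (sceptical, 0), H = (flat, 0.08),
    SH = (sceptical, 0.08).
    """

    prior: str
    tau: float = 0.0

    _LABELS = {
        ("flat", 0.0): "N",
        ("sceptical", 0.0): "S",
        ("flat", TAU_DEFAULT): "H",
        ("sceptical", TAU_DEFAULT): "SH",
    }

    def __post_init__(self) -> None:
        if self.prior not in ("flat", "sceptical"):
            raise ValueError(f"prior must be 'flat' or 'sceptical', got {self.prior!r}")
        if self.tau < 0:
            raise ValueError(f"tau must be non-negative, got {self.tau}")

    @property
    def label(self) -> str:
        return self._LABELS.get((self.prior, self.tau), f"{self.prior}(tau={self.tau:g})")

    @classmethod
    def from_label(cls, label: str, tau: float = TAU_DEFAULT) -> "MethodSpec":
        """Build a method from its canonical label; ``tau`` sets the value used by H/SH."""
        table = {
            "N": cls("flat", 0.0),
            "S": cls("sceptical", 0.0),
            "H": cls("flat", tau),
            "SH": cls("sceptical", tau),
        }
        try:
            return table[label.upper()]
        except KeyError:
            raise ValueError(f"unknown method label {label!r}; expected one of N, S, H, SH") from None


DEFAULT_METHODS = (
    MethodSpec("flat", 0.0),
    MethodSpec("sceptical", 0.0),
    MethodSpec("flat", TAU_DEFAULT),
    MethodSpec("sceptical", TAU_DEFAULT),
)


@dataclass(frozen=True)
class ShrinkageResult:
    """Empirical-Bayes variance factor g_hat and the implied shrinkage s = g/(1+g)."""

    g_hat: float
    s: float = field(init=False)

    def __post_init__(self) -> None:
        if self.g_hat < 0:
            raise ValueError("g_hat must be non-negative")
        object.__setattr__(self, "s", self.g_hat / (1.0 + self.g_hat))


def flat_predictive(z_o: ZEstimate, sigma_r2: float, tau: float = 0.0) -> NormalPredictive:
    """Flat-prior predictive ``N(theta_hat_o, sigma_o^2 + sigma_r^2 + 2 tau^2)``.

    With ``tau = 0`` this reduces to the naive model: same underlying effect
    in both studies and an unbiased original estimate.
    """
    if not sigma_r2 > 0:
        raise ValueError("sigma_r2 must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return NormalPredictive(
        mean=z_o.theta_hat,
        variance=z_o.variance + sigma_r2 + 2.0 * tau**2,
        scale=FISHER_Z,
    )


def g_hat(z_o: ZEstimate, tau: float = 0.0) -> float:
    """Empirical-Bayes estimate ``max(theta_hat_o^2/(sigma_o^2 + tau^2) - 1, 0)``.

    Maximizes the marginal likelihood of the original estimate over the
    g-prior variance factor.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return max(z_o.theta_hat**2 / (z_o.variance + tau**2) - 1.0, 0.0)


def shrinkage_factor(t_o, d=0.0):
    """Evidence-based shrinkage ``s = max(1 - (1 + d)/t_o^2, 0)``.

    For ``d = 0`` this is the classical optimal-shrinkage factor for a normal
    mean; heterogeneity ``d`` induces extra shrinkage.  ``t_o = 0`` gives
    ``s = 0`` (a valid mean-zero forecast, not an error).  Vectorized in
    ``t_o`` and ``d``.
    """
    t_o = np.asarray(t_o, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("d must be non-negative")
    with np.errstate(divide="ignore"):
        s = np.where(t_o == 0.0, 0.0, np.maximum(1.0 - (1.0 + d) / t_o**2, 0.0))
    return s.item() if s.ndim == 0 else s


def sceptical_predictive(z_o: ZEstimate, sigma_r2: float, tau: float = 0.0) -> NormalPredictive:
    """Sceptical (empirical-Bayes g-prior) predictive distribution.

    ``N(s theta_hat_o, s (sigma_o^2 + tau^2) + sigma_r^2 + tau^2)`` with
    ``s = max(1 - (1 + d)/t_o^2, 0)``, ``d = tau^2/sigma_o^2``.  Always at
    least as sharp as the flat-prior predictive.
    """
    if not sigma_r2 > 0:
        raise ValueError("sigma_r2 must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    d = tau**2 / z_o.variance
    s = shrinkage_factor(z_o.t, d)
    return NormalPredictive(
        mean=s * z_o.theta_hat,
        variance=s * (z_o.variance + tau**2) + sigma_r2 + tau**2,
        scale=FISHER_Z,
    )


def predictive_t(t_o, c, d=0.0, prior: str = "flat") -> NormalPredictive:
    """Predictive distribution of the replication test statistic t_r.

    Depends only on the relative quantities: flat prior
    ``N(sqrt(c) t_o, 1 + c (1 + 2 d))``; sceptical prior
    ``N(s sqrt(c) t_o, s c (1 + d) + 1 + c d)``.  Equals the Fisher-z-scale
    predictive rescaled by ``1/sigma_r``.  Vectorized.
    """
    t_o = np.asarray(t_o, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(c <= 0):
        raise ValueError("variance ratio c must be positive")
    if np.any(d < 0):
        raise ValueError("d must be non-negative")
    if prior == "flat":
        mean = np.sqrt(c) * t_o
        variance = 1.0 + c * (1.0 + 2.0 * d)
    elif prior == "sceptical":
        s = shrinkage_factor(t_o, d)
        mean = s * np.sqrt(c) * t_o
        variance = s * c * (1.0 + d) + 1.0 + c * d
    else:
        raise ValueError(f"prior must be 'flat' or 'sceptical', got {prior!r}")
    if mean.ndim == 0:
        mean = mean.item()
        variance = float(variance)
    return NormalPredictive(mean=mean, variance=variance, scale=TEST_STATISTIC)


def prediction_interval(
    pred: NormalPredictive, level: float = 0.95, output_scale: str = FISHER_Z
):
    """Central prediction interval ``mean +/- z_{(1-level)/2} sd``.

    ``output_scale='correlation'`` back-transforms both endpoints with tanh
    (a monotone map, so coverage is preserved); it is only meaningful for a
    Fisher-z-scale predictive.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    q = stats.norm.ppf(0.5 + level / 2.0)
    lower = pred.mean - q * pred.sd
    upper = pred.mean + q * pred.sd
    if output_scale == "correlation":
        if pred.scale != FISHER_Z:
            raise ValueError("correlation-scale intervals require a fisher_z-scale predictive")
        lower, upper = inverse_fisher_z(lower), inverse_fisher_z(upper)
    elif output_scale != pred.scale:
        raise ValueError(f"cannot express a {pred.scale} predictive on scale {output_scale!r}")
    return lower, upper


def replication_probability(
    t_o, c, d=0.0, alpha: float = 0.05, prior: str = "flat", two_sided: bool = False
):
    """Probability of a significant replication in the original's direction.

    The pair must be oriented so that ``t_o > 0``.  Default is the
    same-direction event ``P(t_r > z_{alpha/2})`` under the predictive of
    the replication test statistic; ``two_sided=True`` additionally counts
    the (normally negligible) opposite tail ``P(t_r < -z_{alpha/2})``.
    """
    t_o_arr = np.asarray(t_o, dtype=float)
    if np.any(t_o_arr <= 0):
        raise ValueError("t_o must be positive; orient the pair first")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    pred = predictive_t(t_o, c, d, prior)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    p = stats.norm.sf(z_crit, loc=pred.mean, scale=pred.sd)
    if two_sided:
        p = p + stats.norm.cdf(-z_crit, loc=pred.mean, scale=pred.sd)
    return p.item() if np.ndim(p) == 0 else p


def _power_limit(t_o: float, d: float, prior: str, alpha: float) -> float:
    """Supremum of the replication probability over n_r (i.e. c -> infinity)."""
    if prior == "flat":
        return float(stats.norm.cdf(t_o / math.sqrt(1.0 + 2.0 * d)))
    s = shrinkage_factor(t_o, d)
    b = s * (1.0 + d) + d
    if b == 0.0:  # s = 0 and d = 0: the predictive stays N(0, 1) for every c
        return alpha / 2.0
    return float(stats.norm.cdf(s * t_o / math.sqrt(b)))


def required_replication_n(
    t_o: float,
    n_o: float,
    target_power: float,
    alpha: float = 0.05,
    method: MethodSpec = MethodSpec("flat", 0.0),
    max_n: int = 10**6,
):
    """Smallest replication sample size reaching the target replication probability.

    Returns the minimal integer ``n_r >= 4`` such that the probability of a
    significant same-direction replication is at least ``target_power``, or
    :data:`NOT_ATTAINABLE` when even an infinitely large replication cannot
    reach it (the power is bounded by its ``c -> infinity`` limit; under the
    sceptical prior with ``s = 0`` the forecast is mean zero and only trivial
    targets are attainable).
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if t_o <= 0:
        raise ValueError("t_o must be positive; orient the pair first")
    d = relative_heterogeneity(method.tau, n_o)

    def power(n_r: float) -> float:
        return replication_probability(t_o, variance_ratio(n_o, n_r), d, alpha, method.prior)

    if target_power >= _power_limit(t_o, d, method.prior, alpha):
        return NOT_ATTAINABLE
    # power is monotone increasing in n_r: bracket by doubling, then bisect.
    lo, hi = 4, 8
    if power(lo) >= target_power:
        return lo
    while power(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > max_n:
            return NOT_ATTAINABLE
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
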