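"""Correlation-scale <-> Fisher-z-scale conversions and study-pair containers.

Replication projects report the original and the replication effect estimate
as correlation coefficients ``r`` together with the study sample sizes ``n``.
On the Fisher-z scale, ``theta = atanh(r)``, the estimates are approximately
normally distributed with variance ``1/(n - 3)``, which is what makes normal
predictive distributions (and closed-form scoring of them) available.

This module holds the pure conversions plus the two relative quantities used
throughout the predictive models:

* the variance ratio ``c = sigma_o^2 / sigma_r^2`` (relative precision of the
  replication compared to the original study), and
* the relative between-study heterogeneity ``d = tau^2 / sigma_o^2``.

Sample sizes may be non-integer "effective" sample sizes (as reported by some
projects); any real ``n > 3`` is accepted, with a warning below 4 where the
normal approximation becomes dubious.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StudyPair",
    "ZEstimate",
    "fisher_z",
    "inverse_fisher_z",
    "z_variance",
    "variance_ratio",
    "relative_heterogeneity",
    "orient_pair",
]


def _check_sample_size(n: float, name: str = "n") -> float:
    n = float(n)
    if not math.isfinite(n) or n <= 3:
        raise ValueError(f"{name} must exceed 3 (variance 1/(n-3) must be positive), got {n}")
    if n < 4:
        warnings.warn(
            f"{name}={n} is below 4; the normal approximation on the Fisher-z "
            "scale is unreliable for such small studies",
            stacklevel=3,
        )
    return n


@dataclass(frozen=True)
class StudyPair:
    """One original/replication study pair on the correlation scale.

    ``r_r``/``n_r`` may be missing when a replication is still being designed;
    ``pm_belief`` is an optional externally elicited probability (e.g. from a
    prediction market) that the replication will be significant.
    """

    study_id: str
    r_o: float
    n_o: float
    r_r: float | None = None
    n_r: float | None = None
    pm_belief: float | None = None

    def __post_init__(self) -> None:
        if not abs(self.r_o) < 1:
            raise ValueError(f"r_o must lie in (-1, 1), got {self.r_o}")
        _check_sample_size(self.n_o, "n_o")
        if self.r_r is not None and not abs(self.r_r) < 1:
            raise ValueError(f"r_r must lie in (-1, 1), got {self.r_r}")
        if self.n_r is not None:
            _check_sample_size(self.n_r, "n_r")
        if self.pm_belief is not None and not 0 <= self.pm_belief <= 1:
            raise ValueError(f"pm_belief must lie in [0, 1], got {self.pm_belief}")

    @property
    def has_replication(self) -> bool:
        return self.r_r is not None and self.n_r is not None


@dataclass(frozen=True)
class ZEstimate:
    """An effect estimate on the Fisher-z scale with its sampling variance."""

    theta_hat: float
    variance: float
    n: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be positive, got {self.variance}")
        if not math.isfinite(self.theta_hat):
            raise ValueError("theta_hat must be finite")

    @classmethod
    def from_correlation(cls, r: float, n: float) -> "ZEstimate":
        """Build the Fisher-z estimate ``atanh(r)`` with variance ``1/(n-3)``."""
        return cls(theta_hat=fisher_z(r), variance=z_variance(n), n=float(n))

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    @property
    def t(self) -> float:
        """Test statistic ``theta_hat / sd``."""
        return self.theta_hat / self.sd


def fisher_z(r):
    """Fisher z-transformation ``atanh(r)`` of a correlation coefficient.

    Variance stabilizing and approximately normalizing; strictly increasing
    and odd.  Accepts scalars or arrays; requires ``|r| < 1``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1) or np.any(~np.isfinite(r)):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return out.item() if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Back-transform ``tanh(z)`` from the Fisher-z to the correlation scale."""
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("inverse_fisher_z requires finite input")
    out = np.tanh(z)
    return out.item() if out.ndim == 0 else out


def z_variance(n: float) -> float:
    """Sampling variance ``1/(n - 3)`` of a Fisher-z transformed correlation."""
    n = _check_sample_size(n)
    return 1.0 / (n - 3.0)


def variance_ratio(n_o: float, n_r: float) -> float:
    """Variance ratio ``c = sigma_o^2 / sigma_r^2 = (n_r - 3)/(n_o - 3)``.

    ``c > 1`` means the replication is more precise than the original.
    """
    return z_variance(n_o) / z_variance(n_r)


def relative_heterogeneity(tau: float, n_o: float) -> float:
    """Relative heterogeneity ``d = tau^2 / sigma_o^2 = tau^2 * (n_o - 3)``."""
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    return tau**2 / z_variance(n_o)


def orient_pair(pair: StudyPair) -> StudyPair:
    """Flip the sign of both estimates so that the original is non-negative.

    "Significance in the same direction as the original" is only well defined
    once each pair is oriented; an exactly zero original is left untouched.
    Idempotent.
    """
    if pair.r_o < 0:
        return dataclasses.replace(
            pair,
            r_o=-pair.r_o,
            r_r=None if pair.r_r is None else -pair.r_r,
        )
    return pair
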