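"""Proper scoring rules for normal predictive distributions and binary forecasts.

All scores are negatively oriented: smaller is better.  For a normal
predictive N(mu, v) and realized value y:

* logarithmic score  LS   = -log f(y) = log(2 pi v)/2 + (y - mu)^2 / (2 v)
* quadratic score    QS   = -2 f(y) + integral f^2 = -2 f(y) + 1/(2 sqrt(pi v))
* CRPS (closed form) CRPS = sqrt(v) [ z (2 Phi(z) - 1) + 2 phi(z) - 1/sqrt(pi) ],
  z = (y - mu)/sqrt(v)

For binary forecasts (probability of a significant replication) the Brier
score BS = mean (p_i - o_i)^2 is used, plus its skill-score normalization
BS_n = (BS_0 - BS)/BS_0 against the constant base-rate forecast, which is
positive when the forecasts beat the base rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import NormalPredictive

__all__ = [
    "BinaryForecastSet",
    "log_score",
    "quadratic_score",
    "crps",
    "mean_scores",
    "brier",
    "brier_normalized",
]


@dataclass(frozen=True)
class BinaryForecastSet:
    """Paired probability forecasts and 0/1 outcomes."""

    probabilities: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.probabilities, dtype=float))
        o = np.atleast_1d(np.asarray(self.outcomes, dtype=float))
        if p.shape != o.shape or p.size == 0:
            raise ValueError("probabilities and outcomes must be non-empty and equal length")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.all(np.isin(o, (0.0, 1.0))):
            raise ValueError("outcomes must be 0 or 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "outcomes", o)

    def __len__(self) -> int:
        return self.probabilities.size

    @property
    def base_rate(self) -> float:
        return float(self.outcomes.mean())


def _mv(pred: NormalPredictive):
    return np.asarray(pred.mean, dtype=float), np.asarray(pred.variance, dtype=float)


def log_score(pred: NormalPredictive, y):
    """Negative log predictive density of a normal forecast at y."""
    mu, v = _mv(pred)
    y = np.asarray(y, dtype=float)
    out = 0.5 * np.log(2.0 * np.pi * v) + (y - mu) ** 2 / (2.0 * v)
    return out.item() if out.ndim == 0 else out


def quadratic_score(pred: NormalPredictive, y):
    """Quadratic (density) score -2 f(y) + ||f||^2 of a normal forecast."""
    mu, v = _mv(pred)
    y = np.asarray(y, dtype=float)
    sd = np.sqrt(v)
    out = -2.0 * stats.norm.pdf(y, loc=mu, scale=sd) + 1.0 / (2.0 * sd * np.sqrt(np.pi))
    return out.item() if out.ndim == 0 else out


def crps(pred: NormalPredictive, y):
    """Continuous ranked probability score of a normal forecast, closed form."""
    mu, v = _mv(pred)
    y = np.asarray(y, dtype=float)
    sd = np.sqrt(v)
    z = (y - mu) / sd
    out = sd * (z * (2.0 * stats.norm.cdf(z) - 1.0) + 2.0 * stats.norm.pdf(z) - 1.0 / np.sqrt(np.pi))
    return out.item() if out.ndim == 0 else out


def _batch(preds) -> NormalPredictive:
    """Accept a batch predictive or a sequence of scalar predictives."""
    if isinstance(preds, NormalPredictive):
        return preds
    preds = list(preds)
    if not preds:
        raise ValueError("empty forecast list")
    scale = preds[0].scale
    if any(p.scale != scale for p in preds):
        raise ValueError("all predictives must share one scale")
    return NormalPredictive(
        mean=np.array([p.mean for p in preds], dtype=float),
        variance=np.array([p.variance for p in preds], dtype=float),
        scale=scale,
    )


def mean_scores(preds, ys) -> dict:
    """Arithmetic means of QS, LS, CRPS over paired forecasts and observations."""
    pred = _batch(preds)
    y = np.atleast_1d(np.asarray(ys, dtype=float))
    if y.size == 0 or y.size != np.atleast_1d(np.asarray(pred.mean)).size:
        raise ValueError("forecasts and observations must be non-empty and equal length")
    return {
        "qs": float(np.mean(quadratic_score(pred, y))),
        "ls": float(np.mean(log_score(pred, y))),
        "crps": float(np.mean(crps(pred, y))),
    }


def brier(f: BinaryForecastSet) -> float:
    """Mean Brier score, mean of (p_i - o_i)^2."""
    return float(np.mean((f.probabilities - f.outcomes) ** 2))


def brier_normalized(f: BinaryForecastSet) -> float:
    """Brier skill relative to the constant base-rate forecast, (BS_0 - BS)/BS_0."""
    p0 = f.base_rate
    if p0 in (0.0, 1.0):
        raise ValueError("normalized Brier score is undefined when all outcomes are identical")
    bs0 = float(np.mean((p0 - f.outcomes) ** 2))
    return (bs0 - brier(f)) / bs0
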