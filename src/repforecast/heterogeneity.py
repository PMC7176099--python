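"""Choosing the between-study heterogeneity tau on an interpretable scale.

The heterogeneity standard deviation ``tau`` lives on the Fisher-z scale and
cannot be estimated from a single original study, so a default value has to
be specified.  The device used here maps ``tau`` to the correlation-scale
width of the central 95% range of the study-specific underlying effects:

    delta(tau) = tanh(theta + z_{0.025} tau) - tanh(theta - z_{0.025} tau)

evaluated at an overall effect ``theta = 0``.  A ``tau`` is then chosen so
that ``delta(tau)`` is plausibly small for direct replications — roughly the
size of a medium correlation effect (Cohen's r = 0.3).  The default
``TAU_DEFAULT = 0.08`` gives ``delta ~ 0.311``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import optimize, stats

__all__ = [
    "TAU_DEFAULT",
    "COHEN_SMALL",
    "COHEN_MEDIUM",
    "COHEN_LARGE",
    "TauChoice",
    "delta_of_tau",
    "tau_for_delta",
]

TAU_DEFAULT = 0.08

# Cohen's effect-size anchors on the correlation scale.
COHEN_SMALL = 0.1
COHEN_MEDIUM = 0.3
COHEN_LARGE = 0.5


def delta_of_tau(tau: float, theta: float = 0.0) -> float:
    """Correlation-scale width of the central 95% effect range implied by tau.

    Strictly increasing in ``tau`` with range [0, 2) at ``theta = 0``.
    """
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    q = stats.norm.ppf(0.975)
    return math.tanh(theta + q * tau) - math.tanh(theta - q * tau)


def tau_for_delta(target_width: float, theta: float = 0.0) -> float:
    """Invert :func:`delta_of_tau`: the tau giving a target 95% effect-range width."""
    if not 0 < target_width < 2:
        raise ValueError(f"target_width must lie in (0, 2), got {target_width}")
    hi = 1.0
    while delta_of_tau(hi, theta) < target_width:
        hi *= 2.0
    return optimize.brentq(
        lambda t: delta_of_tau(t, theta) - target_width, 0.0, hi, xtol=1e-10
    )


@dataclass(frozen=True)
class TauChoice:
    """A heterogeneity value together with its correlation-scale 95% width."""

    tau: float
    delta: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", delta_of_tau(self.tau))
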