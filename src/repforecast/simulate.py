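"""Synthetic replication projects from the hierarchical effect-size model.

Each study pair is generated on the Fisher-z scale as

    theta        ~ N(effect_mean, effect_sd^2)        (overall effect)
    theta_o, theta_r | theta ~ N(theta, tau^2)         (study-specific effects)
    theta_hat_k | theta_k    ~ N(theta_k, 1/(n_k - 3)) (estimates)

and reported as correlations ``r = tanh(theta_hat)``.  With ``selection``
enabled, the whole original-study triple (theta, theta_o, theta_hat_o) is
redrawn until the original is two-sided significant at ``selection_alpha``
— file-drawer selection of *studies*, which inflates published originals the
way publication bias does; the replication is then drawn unconditionally.

Defaults: overall effects centred at 0.2 with spread 0.15 on the Fisher-z
scale (small-to-medium correlations, typical for the social-science
replication projects), heterogeneity tau = 0.08 (the package default),
original sample sizes uniform on {20, ..., 100}, and replications of equal
size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heterogeneity import TAU_DEFAULT
from .transforms import StudyPair

__all__ = ["SimConfig", "simulate_pairs"]


@dataclass(frozen=True)
class SimConfig:
    n_pairs: int = 73
    effect_mean: float = 0.2
    effect_sd: float = 0.15
    tau: float = TAU_DEFAULT
    n_o_range: tuple[int, int] = (20, 100)
    n_r_rule: str = "equal"
    n_r_factor: float = 1.0
    selection: bool = False
    selection_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be at least 1")
        if self.effect_sd < 0 or self.tau < 0:
            raise ValueError("effect_sd and tau must be non-negative")
        lo, hi = self.n_o_range
        if lo < 4 or hi < lo:
            raise ValueError("n_o_range must be an increasing interval with lower bound >= 4")
        if self.n_r_rule not in ("equal", "multiplier"):
            raise ValueError("n_r_rule must be 'equal' or 'multiplier'")
        if self.n_r_factor <= 0:
            raise ValueError("n_r_factor must be positive")
        if not 0 < self.selection_alpha < 1:
            raise ValueError("selection_alpha must lie in (0, 1)")


def _simulate_arrays(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    from scipy import stats

    n = config.n_pairs
    lo, hi = config.n_o_range
    n_o = rng.integers(lo, hi + 1, size=n).astype(float)
    if config.n_r_rule == "equal":
        n_r = n_o.copy()
    else:
        n_r = np.maximum(4.0, np.round(n_o * config.n_r_factor))
    sd_o = 1.0 / np.sqrt(n_o - 3.0)
    sd_r = 1.0 / np.sqrt(n_r - 3.0)

    def draw_originals(size):
        theta = rng.normal(config.effect_mean, config.effect_sd, size=size)
        theta_o = rng.normal(theta, config.tau)
        return theta, theta_o

    theta, theta_o = draw_originals(n)
    theta_hat_o = rng.normal(theta_o, sd_o)
    if config.selection:
        z_crit = stats.norm.ppf(1.0 - config.selection_alpha / 2.0)
        pending = np.abs(theta_hat_o) / sd_o <= z_crit
        while pending.any():
            k = int(pending.sum())
            theta_new, theta_o_new = draw_originals(k)
            theta_hat_new = rng.normal(theta_o_new, sd_o[pending])
            theta[pending] = theta_new
            theta_o[pending] = theta_o_new
            theta_hat_o[pending] = theta_hat_new
            pending = np.abs(theta_hat_o) / sd_o <= z_crit
    theta_r = rng.normal(theta, config.tau)
    theta_hat_r = rng.normal(theta_r, sd_r)
    return {
        "n_o": n_o,
        "n_r": n_r,
        "theta_hat_o": theta_hat_o,
        "theta_hat_r": theta_hat_r,
        "theta": theta,
    }


def simulate_pairs(config: SimConfig) -> list[StudyPair]:
    """Generate a synthetic replication project; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    arr = _simulate_arrays(config, rng)
    width = len(str(config.n_pairs))
    return [
        StudyPair(
            study_id=f"sim{i + 1:0{width}d}",
            r_o=float(np.tanh(arr["theta_hat_o"][i])),
            n_o=float(arr["n_o"][i]),
            r_r=float(np.tanh(arr["theta_hat_r"][i])),
            n_r=float(arr["n_r"][i]),
        )
        for i in range(config.n_pairs)
    ]
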