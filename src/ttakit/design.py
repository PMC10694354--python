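"""Trial-design computations: two-proportion sample size and Efron's biased coin.

The sample-size routine targets the classical two-arm comparison of binomial
proportions (any-grade toxicity rate in control vs. experimental arm) with a
two-sided normal-approximation test.  The continuity-corrected (Fleiss)
variant is the default because the uncorrected pooled-variance formula is
known to be anti-conservative for moderate rates; both are exposed.

Randomization is Efron's biased coin, applied independently within each
stratum combination: when the arms are balanced within the stratum the coin
is fair, otherwise the under-represented arm is favoured with probability
``p_bias`` (Efron's classical choice 2/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = ["SampleSizeSpec", "required_sample_size", "CoinState", "efron_assign"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design parameters for a two-proportion comparison.

    Parameters
    ----------
    p_control, p_experimental
        Anticipated event proportions in the two arms; must differ and lie
        strictly inside (0, 1).
    alpha
        Two-sided significance level.
    power
        Target power 1 - beta.
    """

    p_control: float
    p_experimental: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        for name in ("p_control", "p_experimental"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {p}")
        if self.p_control == self.p_experimental:
            raise ValueError("p_control and p_experimental must differ (no detectable effect)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power must be in (0, 1), got {self.power}")


def required_sample_size(
    spec: SampleSizeSpec, *, continuity_correction: bool = True
) -> tuple[int, int]:
    """Per-arm and total sample size for a two-sided two-proportion test.

    The uncorrected per-arm size is the pooled-variance normal approximation

        n = (z_{a/2} sqrt(2 pbar qbar) + z_b sqrt(p1 q1 + p2 q2))^2 / (p1-p2)^2

    and the default applies the Fleiss continuity correction

        n_c = (n / 4) (1 + sqrt(1 + 4 / (n |p1 - p2|)))^2

    before taking the ceiling.  Returns ``(n_per_arm, n_total)``.
    """
    p1, p2 = spec.p_control, spec.p_experimental
    delta = abs(p1 - p2)
    pbar = (p1 + p2) / 2.0
    qbar = 1.0 - pbar
    z_a = norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = norm.ppf(spec.power)
    n = (z_a * math.sqrt(2.0 * pbar * qbar) + z_b * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    n /= delta**2
    if continuity_correction:
        n = (n / 4.0) * (1.0 + math.sqrt(1.0 + 4.0 / (n * delta))) ** 2
    n_per_arm = math.ceil(n - 1e-12)
    return n_per_arm, 2 * n_per_arm


@dataclass
class CoinState:
    """Per-stratum assignment counts for a two-arm biased coin.

    ``counts`` maps a (hashable) stratum key to ``[n_arm0, n_arm1]``.
    """

    p_bias: float = 2.0 / 3.0
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.5 <= self.p_bias <= 1.0:
            raise ValueError(f"p_bias must be in [0.5, 1], got {self.p_bias}")

    def imbalance(self, stratum) -> int:
        c = self.counts.get(stratum, [0, 0])
        return c[0] - c[1]


def efron_assign(state: CoinState, stratum, rng: np.random.Generator) -> int:
    """Assign the next subject in ``stratum`` to arm 0 or 1, updating ``state``.

    Balanced within-stratum counts give a fair coin; otherwise the
    under-represented arm is chosen with probability ``state.p_bias``.
    """
    c = state.counts.setdefault(stratum, [0, 0])
    if c[0] == c[1]:
        arm = int(rng.random() < 0.5)
    else:
        under = 0 if c[0] < c[1] else 1
        arm = under if rng.random() < state.p_bias else 1 - under
    c[arm] += 1
    return arm
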