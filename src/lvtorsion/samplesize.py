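"""Two-group sample-size calculation from test-retest difference SDs.

n = f(alpha, P) * sigma^2 * 2 / delta^2, where f is the squared sum of the
standard-normal quantiles for the significance level and power, sigma the SD
of the inter-test differences, and delta the difference to detect.
"""

from __future__ import annotations

import math

from scipy.stats import norm

__all__ = ["factor_f", "required_n", "modality_comparison", "sample_size_table"]


def factor_f(alpha: float, power: float) -> float:
    """Power-formula factor f = (z_{1-alpha/2} + z_P)^2, unrounded.

    Round to one decimal for display (10.5 at alpha 0.05, power 0.90).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not (0.0 < power < 1.0):
        raise ValueError("power must be in (0, 1)")
    return float((norm.ppf(1.0 - alpha / 2.0) + norm.ppf(power)) ** 2)


def required_n(sigma: float, delta: float, alpha: float = 0.05,
               power: float = 0.90) -> int:
    """Per-group sample size, ceiling-rounded and clamped to >= 1.

    Uses the unrounded factor f.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    raw = factor_f(alpha, power) * sigma**2 * 2.0 / delta**2
    return max(1, math.ceil(raw))


def modality_comparison(n_this: int, n_published) -> list[int]:
    """Percent reduction in required n versus published values (nearest int)."""
    if n_this < 1:
        raise ValueError("n_this must be >= 1")
    out = []
    for n_pub in n_published:
        if n_pub < 1:
            raise ValueError("published n must be >= 1")
        out.append(round(100.0 * (n_pub - n_this) / n_pub))
    return out


def sample_size_table(sigmas: dict, delta: float, alpha: float = 0.05,
                      power: float = 0.90) -> dict:
    """Required n per labelled sigma (e.g. one row per protocol)."""
    return {label: required_n(sigma, delta, alpha=alpha, power=power)
            for label, sigma in sigmas.items()}
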