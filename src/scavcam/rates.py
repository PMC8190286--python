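"""Displacement-rate estimation with exact binomial confidence intervals
and a two-rate comparison.

Rates are reported both as proportions with Clopper–Pearson (exact) 95%
intervals and in the field's reciprocal "1 per k visits" presentation.
Because the original analysis did not state its CI or comparison method,
:func:`compare_rates` reports two complementary answers: a one-sided Fisher
exact test on the 2x2 event table, and the Monte-Carlo posterior
probability that the second rate exceeds the first under independent
uniform priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass
class RateEstimate:
    events: int
    trials: int
    rate: float
    ci_low: float
    ci_high: float
    conf_level: float

    @property
    def reciprocal(self) -> str:
        """'1 per k' presentation; '0' when no events were observed."""
        if self.events == 0:
            return "0"
        return f"1 per {round(self.trials / self.events)}"


@dataclass
class RateComparison:
    estimate_1: RateEstimate
    estimate_2: RateEstimate
    p_fisher_one_sided: float
    p_posterior: float
    direction: str


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial interval from beta quantiles.

    Endpoints are clamped to [0, 1]; x = 0 gives a lower bound of exactly 0
    and x = n an upper bound of exactly 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    alpha = 1.0 - conf
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return max(0.0, low), min(1.0, high)


def proportion_ci(x: int, n: int, conf: float = 0.95, method: str = "exact") -> tuple[float, float]:
    """Binomial proportion CI by 'wald', 'wilson', or 'exact' (Clopper–Pearson)."""
    sm_method = {"wald": "normal", "wilson": "wilson", "exact": "beta"}[method]
    low, high = proportion_confint(x, n, alpha=1.0 - conf, method=sm_method)
    return float(np.clip(low, 0, 1)), float(np.clip(high, 0, 1))


def reciprocal_rate(x: int, n: int) -> int:
    """Round(n / x): the k of the '1 per k trials' presentation."""
    if x < 1:
        raise ValueError("reciprocal presentation requires at least one event")
    return round(n / x)


def rate_estimate(x: int, n: int, conf: float = 0.95) -> RateEstimate:
    low, high = clopper_pearson(x, n, conf)
    return RateEstimate(events=x, trials=n, rate=x / n, ci_low=low, ci_high=high, conf_level=conf)


def compare_rates(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    conf: float = 0.95,
    n_draws: int = 200_000,
    seed: int = 0,
) -> RateComparison:
    """Compare two event rates x1/n1 and x2/n2.

    Reports (a) the one-sided Fisher exact p-value for rate 1 exceeding
    rate 2, from the table [[x1, n1-x1], [x2, n2-x2]], and (b) the
    Monte-Carlo posterior probability P(p2 >= p1 | data) under independent
    Beta(x+1, n-x+1) posteriors (uniform priors), with >= 1e5 draws and a
    fixed seed.
    """
    if n_draws < 100_000:
        raise ValueError("n_draws must be at least 1e5 for a stable posterior probability")
    e1, e2 = rate_estimate(x1, n1, conf), rate_estimate(x2, n2, conf)
    _, p_fisher = stats.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]], alternative="greater")
    rng = np.random.default_rng(seed)
    p1 = rng.beta(x1 + 1, n1 - x1 + 1, n_draws)
    p2 = rng.beta(x2 + 1, n2 - x2 + 1, n_draws)
    p_post = float(np.mean(p2 >= p1))
    direction = "rate1>rate2" if e1.rate > e2.rate else ("rate2>rate1" if e2.rate > e1.rate else "equal")
    return RateComparison(
        estimate_1=e1,
        estimate_2=e2,
        p_fisher_one_sided=float(p_fisher),
        p_posterior=p_post,
        direction=direction,
    )
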