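"""Sample-size reasoning for best-worst scaling cohort comparisons.

With ~50 respondents per cohort, the study-planning question is which
standardized mean difference a two-sample comparison can detect.  The answer
for n = 50 per group at two-sided alpha = 0.05 and 80% power is a Cohen's d
of about 0.57, which is why cohorts of that size were considered sufficient.
"""

from __future__ import annotations

from statsmodels.stats.power import TTestIndPower

__all__ = ["minimal_detectable_difference"]


def minimal_detectable_difference(
    n_per_group: int, alpha: float = 0.05, power: float = 0.8
) -> float:
    """Smallest standardized two-sample mean difference detectable.

    Solves the two-sided independent-samples t-test power equation for the
    effect size (difference in within-group standard deviation units).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 observations per group")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    return float(
        TTestIndPower().solve_power(
            effect_size=None,
            nobs1=n_per_group,
            ratio=1.0,
            alpha=alpha,
            power=power,
            alternative="two-sided",
        )
    )
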