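"""Gated two-sample comparison: F-test gate, then Student's or Welch's t.

Group means (per-dish stain densities, wettability indexes, contact angles)
are compared pairwise. Homoscedasticity is first checked with a two-sided
variance-ratio F-test; when it is not rejected the pooled-variance Student
t-test is used, otherwise Welch's t-test with Welch–Satterthwaite degrees of
freedom. Both tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError


@dataclass
class ComparisonResult:
    test_used: str  # "student" or "welch"
    f_statistic: float
    f_p_value: float
    t_statistic: float
    t_p_value: float
    n1: int
    n2: int
    alpha_gate: float

    @property
    def significance_tier(self) -> str:
        """Conventional star notation for the t-test p-value."""
        p = self.t_p_value
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "ns"


def f_test(x, y) -> tuple[float, float]:
    """Two-sided variance-ratio F-test with the larger variance on top.

    Returns ``(F, p)`` where ``F = max(s1², s2²)/min(s1², s2²)`` and ``p`` is
    twice the upper-tail probability, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each sample needs at least two observations")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vx == 0.0 or vy == 0.0:
        raise ParameterError("constant sample; variance ratio undefined")
    if vx >= vy:
        num, den, dfn, dfd = vx, vy, x.size - 1, y.size - 1
    else:
        num, den, dfn, dfd = vy, vx, y.size - 1, x.size - 1
    f_stat = num / den
    p = min(1.0, 2.0 * float(sps.f.sf(f_stat, dfn, dfd)))
    return f_stat, p


def gated_t_test(x, y, alpha_gate: float = 0.05) -> ComparisonResult:
    """F-test-gated two-sample t-test.

    If the F-test does not reject equal variances at ``alpha_gate``, the
    pooled-variance Student t-test is applied; otherwise Welch's t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    f_stat, f_p = f_test(x, y)
    equal_var = f_p >= alpha_gate
    t_stat, t_p = sps.ttest_ind(x, y, equal_var=equal_var)
    return ComparisonResult(
        test_used="student" if equal_var else "welch",
        f_statistic=f_stat,
        f_p_value=f_p,
        t_statistic=float(t_stat),
        t_p_value=float(t_p),
        n1=int(x.size),
        n2=int(y.size),
        alpha_gate=alpha_gate,
    )
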