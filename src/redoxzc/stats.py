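"""Regression, exact binomial sign tests, and slope-tally tables.

Each 16S data set yields one ordinary-least-squares regression of community
Z_C on Eh7 (in volts, so slopes print in 1/V).  Slopes are summarized as
m +/- MOE95 where [m - MOE95, m + MOE95] is the 95% confidence interval
(t distribution, N-2 degrees of freedom).  The sign of the slope across
data sets is then treated as a Bernoulli trial with null probability 0.5:
the probability of observing at least N_pos positive slopes out of N_tot is
an exact one-sided binomial tail, computed with integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionFit",
    "BinomialTally",
    "ols_fit",
    "binom_tail",
    "significance_filter",
    "tally_table",
    "group_zc_ttest",
    "format_p",
]


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit of Z_C against Eh7 (V): slope m, 95% margin of error,
    Pearson r, intercept; labels identify the source data set."""

    N: int
    m: float                  # slope per volt
    moe95: float              # half-width of the 95% CI, per volt
    r: float                  # Pearson correlation
    intercept: float
    dataset: str = ""
    domain: str = ""
    environment: str = ""

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError("a regression fit needs N >= 3")
        if self.moe95 < 0:
            raise ValueError("margin of error cannot be negative")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("Pearson r outside [-1, 1]")

    @property
    def ci(self) -> tuple[float, float]:
        return self.m - self.moe95, self.m + self.moe95

    @property
    def significant(self) -> bool:
        """True when the 95% CI excludes zero (both ends share a sign)."""
        lo, hi = self.ci
        return lo > 0 or hi < 0


@dataclass(frozen=True)
class BinomialTally:
    label: str
    N_tot: int
    N_pos: int
    N_neg: int
    P: float

    def __post_init__(self) -> None:
        if self.N_pos + self.N_neg != self.N_tot:
            raise ValueError("N_pos + N_neg must equal N_tot")
        if not 0.0 < self.P <= 1.0:
            raise ValueError("P must be in (0, 1]")


def ols_fit(
    x: Sequence[float],
    y: Sequence[float],
    dataset: str = "",
    domain: str = "",
    environment: str = "",
) -> RegressionFit:
    """Ordinary least squares of y (Z_C) on x (Eh7 in volts).

    ``moe95 = t(0.975, N-2) * SE(slope)``; a perfect linear relation gives
    moe95 = 0 and |r| = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("OLS requires N >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    ss_res = float((resid**2).sum())
    se_slope = np.sqrt(ss_res / (n - 2) / sxx)
    moe95 = float(sps.t.ppf(0.975, n - 2) * se_slope)
    syy = float(((y - ym) ** 2).sum())
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    return RegressionFit(
        N=n, m=float(slope), moe95=moe95, r=float(r), intercept=float(intercept),
        dataset=dataset, domain=domain, environment=environment,
    )


def binom_tail(n: int, k: int) -> float:
    """Exact one-sided binomial tail P(X >= k) for X ~ Binomial(n, 1/2).

    Computed by integer summation of binomial coefficients, so the value is
    exact to the last float bit; ``binom_tail(n, 0) = 1`` and
    ``binom_tail(n, n) = 0.5**n``.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    numerator = sum(comb(n, i) for i in range(k, n + 1))
    return numerator / 2**n


def significance_filter(fits: Iterable[RegressionFit]) -> list[RegressionFit]:
    """Keep only fits whose 95% CI excludes zero (CI endpoints share a sign)."""
    return [f for f in fits if f.significant]


def tally_table(
    fits: Sequence[RegressionFit],
    filtered: bool = False,
    environments: Sequence[str] | None = None,
) -> list[BinomialTally]:
    """Per-environment sign tallies of regression slopes, plus a Total row.

    ``P = binom_tail(N_tot, N_pos)``: the chance of at least this many
    positive slopes under a 50% null.  With ``filtered=True`` only fits
    whose CI excludes zero are counted.
    """
    pool = significance_filter(fits) if filtered else list(fits)
    if environments is None:
        seen: list[str] = []
        for f in fits:
            if f.environment not in seen:
                seen.append(f.environment)
        environments = seen
    rows: list[BinomialTally] = []
    for env in environments:
        group = [f for f in pool if f.environment == env]
        if not group:
            continue
        n_pos = sum(1 for f in group if f.m > 0)
        rows.append(BinomialTally(
            label=env, N_tot=len(group), N_pos=n_pos, N_neg=len(group) - n_pos,
            P=binom_tail(len(group), n_pos),
        ))
    if pool:
        n_pos = sum(1 for f in pool if f.m > 0)
        rows.append(BinomialTally(
            label="Total", N_tot=len(pool), N_pos=n_pos, N_neg=len(pool) - n_pos,
            P=binom_tail(len(pool), n_pos),
        ))
    return rows


def group_zc_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided pooled-variance (Student) t-test P value for a difference in
    mean Z_C between two groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def format_p(p: float) -> str:
    """Table-style P value formatting.

    At or above 1e-3: three decimals with round-half-even (0.8125 ->
    '0.812').  Below 1e-3: five decimals (6.5e-5 -> '0.00007'), falling
    back to one significant figure for values that would print as zero.
    Raw values should be kept alongside the printed form.
    """
    if not 0 <= p <= 1:
        raise ValueError("P must be in [0, 1]")
    if p >= 1e-3:
        return f"{round(p, 3):.3g}"
    if round(p, 5) > 0:
        return f"{round(p, 5):.5f}"
    return np.format_float_positional(
        p, precision=1, unique=False, fractional=False, trim="-"
    )
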