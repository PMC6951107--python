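"""Inferential layer: t-tests, pooled Cohen's d, JZS Bayes factors, power.

The Bayes factor is the Jeffreys-Zellner-Siow one-sample test: a Cauchy prior
(centred at zero, scale ``r``) on the standardized effect under the
alternative against a point null, evaluated by numerical integration of the
noncentral-t marginal likelihood. One-sided alternatives truncate the prior
to the stated sign. The "exceedance probability" reported alongside a Bayes
factor is the posterior probability of the favored hypothesis at equal prior
odds, BF / (1 + BF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    d: float  # one-sample effect size, mean / sd

    def __str__(self):
        return f"t({self.df}) = {self.t:.3f}, p = {self.p:.4g}, d = {self.d:.3f}"


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-tailed one-sample t-test (paired tests pass the differences)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
        raise ValueError("zero variance")
    res = stats.ttest_1samp(x, mu0)
    return TTestResult(
        t=float(res.statistic),
        df=int(x.size - 1),
        p=float(res.pvalue),
        d=float((x.mean() - mu0) / sd),
    )


def cohens_d_pooled(x, y) -> float:
    """Mean difference divided by the SD pooled across the two conditions.

    Used as the between-subjects-style effect size for every two-condition
    contrast, regardless of whether the design is within- or between-subjects.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    pooled_sd = np.sqrt(pooled_var)
    if pooled_sd == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / pooled_sd)


@dataclass
class BayesFactorResult:
    bf10: float  # evidence for the (possibly one-sided) alternative
    direction: str  # 'two_sided' | 'decrease' | 'increase'
    scale: float
    t: float
    n: int

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10

    @property
    def favored(self) -> str:
        return "alternative" if self.bf10 >= 1.0 else "null"

    @property
    def exceedance(self) -> float:
        """Posterior probability of the favored hypothesis at equal prior odds."""
        bf = max(self.bf10, self.bf01)
        return bf / (1.0 + bf)

    def __str__(self):
        bf = self.bf10 if self.favored == "alternative" else self.bf01
        return (
            f"BF = {bf:.2f} in favor of the {self.favored} "
            f"(exceedance probability = {self.exceedance:.2f}; "
            f"Cauchy scale r = {self.scale})"
        )


def _jzs_marginal(t: float, df: int, n: int, scale: float, lo: float, hi: float) -> float:
    """Marginal likelihood of t under a Cauchy(0, scale) prior on delta in (lo, hi)."""
    prior_mass = stats.cauchy.cdf(hi, 0, scale) - stats.cauchy.cdf(lo, 0, scale)

    def integrand(delta):
        return (
            stats.nct.pdf(t, df, delta * np.sqrt(n))
            * stats.cauchy.pdf(delta, 0, scale)
            / prior_mass
        )

    m, err = integrate.quad(integrand, lo, hi, limit=200)
    if not np.isfinite(m) or m <= 0:
        raise FloatingPointError(
            f"JZS marginal likelihood not finite (t={t}, n={n}, got {m}, err {err})"
        )
    return m


def jzs_bayes_factor(
    differences, scale: float = 0.707, direction: str = "two_sided"
) -> BayesFactorResult:
    """JZS Bayes factor for a one-sample (or paired-differences) test.

    ``direction='decrease'`` restricts the Cauchy prior to negative
    standardized effects, ``'increase'`` to positive ones; the null hypothesis
    is always the point null of no effect.
    """
    x = np.asarray(differences, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance")
    n = int(x.size)
    df = n - 1
    t = float(x.mean() / (x.std(ddof=1) / np.sqrt(n)))

    bounds = {
        "two_sided": (-np.inf, np.inf),
        "decrease": (-np.inf, 0.0),
        "increase": (0.0, np.inf),
    }
    if direction not in bounds:
        raise ValueError(f"unknown direction {direction!r}")
    m1 = _jzs_marginal(t, df, n, scale, *bounds[direction])
    m0 = stats.t.pdf(t, df)
    return BayesFactorResult(bf10=m1 / m0, direction=direction, scale=scale, t=t, n=n)


def power_one_sample_t(n: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact power of a one-sample t-test at effect size d via the noncentral t."""
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    ncp = d * np.sqrt(n)
    if tails == 2:
        crit = stats.t.ppf(1 - alpha / 2, df)
        power = float(
            1 - stats.nct.cdf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
        )
    else:
        crit = stats.t.ppf(1 - alpha, df)
        power = float(1 - stats.nct.cdf(crit, df, ncp))
    if np.isnan(power):  # scipy's noncentral t underflows at extreme ncp
        power = 1.0 if ncp > crit else 0.0
    return power


def required_sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.85,
    tails: int = 2,
    n_max: int = 100_000,
) -> int:
    """Smallest n whose exact one-sample t-test power reaches the target.

    By convention the minimum returned value is 2 (a t-test needs at least
    two observations), so very large effects floor there.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_one_sample_t(n, d, alpha, tails) >= power:
            return n
    raise ValueError(f"requested power not reached by n = {n_max}")
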