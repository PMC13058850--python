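"""Group-level inference: t-tests, effect sizes, JZS Bayes factors,
Bonferroni families, Pearson correlations with Fisher-z intervals.

One-sample and Welch tests default to the one-sided upper-tail alternative
(effect greater than the null value), matching the directional hypotheses a
positive grid-like signal implies.  Bayes factors are the default two-sided
JZS t-test Bayes factors with a zero-centered Cauchy prior of width r on the
standardized effect size, computed by numerical integration of the
noncentral-t marginal likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import integrate
from scipy import stats as sps

DEFAULT_CAUCHY_R = 0.707


class StatsError(ValueError):
    pass


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    d: float
    bf10: float
    bf01: float
    n: Optional[int] = None
    n1: Optional[int] = None
    n2: Optional[int] = None
    alternative: str = "greater"
    family: Optional[str] = None
    alpha_corrected: Optional[float] = None


def _p_value(t: float, df: float, alternative: str) -> float:
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    if alternative == "two-sided":
        return float(2.0 * sps.t.sf(abs(t), df))
    raise StatsError(f"unknown alternative: {alternative!r}")


def p_from_t(t: float, df: float, alternative: str = "greater") -> float:
    """p-value for a t statistic with given degrees of freedom."""
    if df <= 0:
        raise StatsError("df must be positive")
    return _p_value(float(t), float(df), alternative)


def cohens_d_from_t(t: float, n: int, n2: Optional[int] = None) -> float:
    """Effect size from a t statistic: t/sqrt(n) for one sample,
    t*sqrt(1/n1 + 1/n2) for two independent samples."""
    if n2 is None:
        return float(t) / np.sqrt(n)
    return float(t) * np.sqrt(1.0 / n + 1.0 / n2)


def jzs_bayes_factor(
    t: float,
    n: int,
    n2: Optional[int] = None,
    r: float = DEFAULT_CAUCHY_R,
) -> Tuple[float, float]:
    """Default (two-sided) JZS t-test Bayes factor with Cauchy prior width r.

    Returns (bf10, bf01).  One-sample: ``n`` observations, df = n - 1,
    effective sample size N = n.  Two-sample (pooled-t formulation): df =
    n + n2 - 2, N = n*n2/(n + n2).  bf10 is the marginal likelihood of t
    under delta ~ Cauchy(0, r) divided by its likelihood under delta = 0.
    The Cauchy prior is expanded as a normal scale mixture, giving a
    one-dimensional integral over the mixing variance g whose integrand is
    evaluated as a likelihood *ratio* in log space -- stable for arbitrarily
    large |t|, where the noncentral-t density itself under- or overflows.
    """
    if not np.isfinite(t):
        raise StatsError("t must be finite")
    if n < 2:
        raise StatsError("need n >= 2")
    if n2 is None:
        nu, n_eff = n - 1.0, float(n)
    else:
        if n2 < 2:
            raise StatsError("need n2 >= 2")
        nu, n_eff = n + n2 - 2.0, n * n2 / (n + n2)
    t2 = t * t
    log_null = np.log1p(t2 / nu)

    def integrand(u):
        # g = e^u: the log substitution keeps the quadrature stable when the
        # integrand mass sits at very large g (huge |t|)
        with np.errstate(over="ignore", divide="ignore"):
            g = np.exp(u)
            q = 1.0 + n_eff * g * r * r
            log_ratio = 0.5 * (nu + 1.0) * (log_null - np.log1p(t2 / (nu * q)))
            out = np.exp(
                log_ratio - 0.5 * np.log(q) - 0.5 * u - 0.5 / g
            ) / np.sqrt(2.0 * np.pi)
        return out if np.isfinite(out) else 0.0

    bf10, err = integrate.quad(
        integrand, -np.inf, np.inf, epsabs=0.0, epsrel=1e-9, limit=300
    )
    if bf10 <= 0 or not np.isfinite(bf10) or err / bf10 > 1e-6:
        raise StatsError(
            f"Bayes-factor integration did not converge (value={bf10}, abserr={err})"
        )
    return float(bf10), float(1.0 / bf10)


def one_sample_test(
    values,
    null_value: float = 0.0,
    alternative: str = "greater",
    cauchy_r: float = DEFAULT_CAUCHY_R,
    compute_bf: bool = True,
) -> TestResult:
    """One-sample t-test with Cohen's d = t/sqrt(n) and the JZS Bayes factor.

    ``compute_bf=False`` skips the Bayes-factor quadrature (useful in large
    calibration loops) and reports bf10 = bf01 = NaN.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise StatsError("need at least 2 observations")
    if np.std(x, ddof=1) == 0:
        raise StatsError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(x, null_value, alternative=alternative)
    t, df = float(res.statistic), n - 1
    d = t / np.sqrt(n)
    if compute_bf:
        bf10, bf01 = jzs_bayes_factor(t, n, r=cauchy_r)
    else:
        bf10 = bf01 = float("nan")
    return TestResult(
        t=t, df=df, p=float(res.pvalue), d=d, bf10=bf10, bf01=bf01,
        n=n, alternative=alternative,
    )


def welch_test(
    group_a,
    group_b,
    alternative: str = "greater",
    cauchy_r: float = DEFAULT_CAUCHY_R,
) -> TestResult:
    """Welch's unequal-variance t-test (a vs b) with pooled-sd Cohen's d.

    The Bayes factor uses the pooled-t JZS two-sample formula with effective
    sample size n1*n2/(n1+n2), the convention of common Bayesian t-test
    tooling, even though the frequentist statistic is Welch's.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise StatsError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    t = float(res.statistic)
    df = float(res.df)
    sp = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    d = float((a.mean() - b.mean()) / sp)
    bf10, bf01 = jzs_bayes_factor(t, a.size, n2=b.size, r=cauchy_r)
    return TestResult(
        t=t, df=df, p=float(res.pvalue), d=d, bf10=bf10, bf01=bf01,
        n1=a.size, n2=b.size, alternative=alternative,
    )


def bonferroni_families(tests, families) -> dict:
    """Per-family Bonferroni thresholds alpha = 0.05 / family size.

    ``tests`` maps test ids to p-values; ``families`` maps test ids to family
    labels.  Every test must belong to a family.  Returns
    {test_id: (family, alpha_corrected, significant)}.
    """
    unassigned = [t for t in tests if t not in families]
    if unassigned:
        raise StatsError(f"tests without a family assignment: {unassigned}")
    sizes: dict = {}
    for tid in tests:
        sizes[families[tid]] = sizes.get(families[tid], 0) + 1
    out = {}
    for tid, p in tests.items():
        fam = families[tid]
        alpha = 0.05 / sizes[fam]
        out[tid] = (fam, alpha, bool(p < alpha))
    return out


def pearson_ci(x, y, confidence: float = 0.95):
    """Pearson correlation with a Fisher-z confidence interval.

    Returns (r, (lo, hi)).  At |r| = 1 the interval degenerates to (r, r).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise StatsError("need paired samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("zero variance: correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-15:
        return r, (r, r)
    zcrit = sps.norm.ppf(0.5 + confidence / 2.0)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(x.size - 3)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return r, (float(lo), float(hi))
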