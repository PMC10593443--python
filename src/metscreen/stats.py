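"""Inferential statistics used by the screening analysis.

Two-sample t-tests (Welch by default, pooled available), Pearson
correlation, and binomial-proportion confidence intervals. The t-test is
computed from sufficient statistics so that the raw-data and
summary-statistic entry points share one code path; the correlation and
proportion intervals delegate to scipy/statsmodels.

All p-values are two-sided. Report layers mark ``*`` for p < 0.05 and
``**`` for p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TTestResult",
    "CorrResult",
    "PropCI",
    "t_test",
    "t_test_from_summary",
    "pearson_corr",
    "pearson_pvalue_from_r",
    "proportion_ci",
    "significance_star",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    se_diff: float
    variant: str


@dataclass(frozen=True)
class CorrResult:
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class PropCI:
    p_hat: float
    n: int
    lower: float
    upper: float
    method: str


_CI_METHODS = {"wilson": "wilson", "wald": "normal", "clopper_pearson": "beta"}


def significance_star(p: float) -> str:
    """Table footnote convention: ``**`` p<0.001, ``*`` p<0.05, else ''."""
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def t_test_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "welch",
) -> TTestResult:
    """Independent two-sample t-test from sufficient statistics.

    ``variant="welch"`` uses the Welch–Satterthwaite approximation (no
    equal-variance assumption, possibly fractional df); ``"pooled"`` is
    the classical equal-variance form with df = n1 + n2 - 2.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    for name, v in (("sd1", sd1), ("sd2", sd2)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    for name, v in (("n1", n1), ("n2", n2)):
        if not v >= 2:
            raise ValueError(f"{name} must be >= 2, got {v}")

    v1, v2 = sd1**2 / n1, sd2**2 / n2
    mean_diff = mean1 - mean2
    if variant == "welch":
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    t = mean_diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p), mean_diff=float(mean_diff), se_diff=float(se), variant=variant)


def t_test(group1, group2, variant: str = "welch") -> TTestResult:
    """Independent two-sample t-test on raw values."""
    x = np.asarray(group1, float)
    y = np.asarray(group2, float)
    for name, g in (("group1", x), ("group2", y)):
        if g.size < 2:
            raise ValueError(f"{name} needs >= 2 values")
        if np.std(g, ddof=1) == 0:
            raise ValueError(f"{name} has zero variance")
    return t_test_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size, variant=variant
    )


def pearson_corr(x, y) -> CorrResult:
    """Pearson correlation with a two-sided p-value (t with n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector")
    res = sps.pearsonr(x, y)
    return CorrResult(r=float(res.statistic), n=int(x.size), p=float(res.pvalue))


def pearson_pvalue_from_r(r: float, n: int) -> float:
    """Two-sided p for a given correlation and sample size.

    Uses t = r*sqrt(n-2)/sqrt(1-r**2) with n-2 df — handy for checking
    printed (r, p) pairs without the raw data.
    """
    if not -1 < r < 1:
        return 0.0 if abs(r) == 1 else float("nan")
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def proportion_ci(successes: int, n: int, method: str = "wilson") -> PropCI:
    """95% binomial-proportion interval (wilson / wald / clopper_pearson)."""
    if method not in _CI_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_CI_METHODS)}")
    if not 0 <= successes <= n or n < 1:
        raise ValueError(f"invalid counts: {successes}/{n}")
    lo, hi = proportion_confint(successes, n, alpha=0.05, method=_CI_METHODS[method])
    return PropCI(
        p_hat=successes / n,
        n=int(n),
        lower=float(np.clip(lo, 0, 1)),
        upper=float(np.clip(hi, 0, 1)),
        method=method,
    )
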