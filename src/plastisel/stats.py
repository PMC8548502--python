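"""Shared classical statistics used by several analysis stages.

Two-proportion and Hardy-Weinberg chi-square statistics follow the
textbook continuity-corrected forms (equivalent to R's ``prop.test`` and
the 1-df goodness-of-fit test), so the enrichment and deviation scans
elsewhere in the package report values directly comparable to standard
tooling.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "two_proportion_test",
    "hwe_chisquare",
    "welch_t_test",
    "bh_adjust",
    "wilson_interval",
]


def two_proportion_test(count_a: int, n_a: int, count_b: int, n_b: int,
                        correction: bool = True) -> dict:
    """Two-sample equality-of-proportions chi-square test.

    With ``correction=True`` this applies the Yates continuity correction
    and matches R's ``prop.test(c(count_a, count_b), c(n_a, n_b))``.

    Returns a dict with ``chi2``, ``p``, ``prop_a``, ``prop_b``, ``df``.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValidationError("both samples must be non-empty")
    if not (0 <= count_a <= n_a and 0 <= count_b <= n_b):
        raise ValidationError("counts must lie within sample sizes")
    p_a = count_a / n_a
    p_b = count_b / n_b
    p_pool = (count_a + count_b) / (n_a + n_b)
    denom = p_pool * (1.0 - p_pool) * (1.0 / n_a + 1.0 / n_b)
    if denom == 0.0:
        chi2 = 0.0
    else:
        diff = abs(p_a - p_b)
        if correction:
            diff = max(0.0, diff - 0.5 * (1.0 / n_a + 1.0 / n_b))
        chi2 = diff * diff / denom
    return {
        "chi2": float(chi2),
        "df": 1,
        "p": float(sps.chi2.sf(chi2, df=1)),
        "prop_a": float(p_a),
        "prop_b": float(p_b),
    }


def hwe_chisquare(n_hom_ref: int, n_het: int, n_hom_alt: int) -> dict:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg genotype
    proportions expected from the observed allele frequencies.

    Monomorphic sites (allele frequency 0 or 1) are returned with chi2=0,
    p=1. Expected cell counts below 5 set ``low_count`` but the statistic is
    still computed.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (counts < 0).any():
        raise ValidationError("genotype counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise ValidationError("no genotypes observed")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return {"chi2": 0.0, "p": 1.0, "df": 1, "low_count": False}
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return {
        "chi2": chi2,
        "p": float(sps.chi2.sf(chi2, df=1)),
        "df": 1,
        "low_count": bool((expected < 5).any()),
    }


def welch_t_test(x, y) -> dict:
    """Welch two-sample t-test (unequal variances), with a documented guard
    for the degenerate zero-variance case.

    When both groups have zero variance, the Welch denominator vanishes: if
    the means differ the test is reported as an extreme rejection (t=inf,
    p=0) with ``degenerate=True``; identical constant groups give t=0, p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("Welch test needs at least 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return {"t": 0.0, "df": float(x.size + y.size - 2), "p": 1.0,
                    "mean_x": float(x.mean()), "mean_y": float(y.mean()),
                    "degenerate": True}
        return {"t": float(np.inf) * np.sign(x.mean() - y.mean()),
                "df": float(x.size + y.size - 2), "p": 0.0,
                "mean_x": float(x.mean()), "mean_y": float(y.mean()),
                "degenerate": True}
    res = sps.ttest_ind(x, y, equal_var=False)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "mean_x": float(x.mean()),
        "mean_y": float(y.mean()),
        "degenerate": False,
    }


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def wilson_interval(count: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score 95% (by default) confidence interval for a proportion."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(count, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)
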