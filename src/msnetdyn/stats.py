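"""Group-level statistics: Welch t-tests, Pearson correlation, optional FDR."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupStatsResult:
    metric: str
    t: float
    df: float
    p: float
    effect: float          # Cohen's d (pooled SD)
    significant: bool
    alpha: float = 0.05


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    undefined: bool = False


def two_sample_test(
    x, y, alpha: float = 0.05, equal_var: bool = False, metric: str = ""
) -> GroupStatsResult:
    """Independent-samples t-test (Welch by default) with Cohen's d.

    The degenerate case of zero variance in both samples with equal means
    reports t = 0, p = 1 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0 and x.mean() == y.mean():
        t, p, df = 0.0, 1.0, float(x.size + y.size - 2)
    else:
        res = sstats.ttest_ind(x, y, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        if equal_var:
            df = float(x.size + y.size - 2)
        else:
            nx, ny = x.size, y.size
            df = (vx / nx + vy / ny) ** 2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
    pooled = np.sqrt(((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2))
    d = (x.mean() - y.mean()) / pooled if pooled > 0 else 0.0
    return GroupStatsResult(
        metric=metric, t=t, df=float(df), p=p, effect=float(d),
        significant=bool(p < alpha), alpha=alpha,
    )


def correlation(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(r=np.nan, p=np.nan, n=x.size, undefined=True)
    r, p = sstats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=x.size)


def bh_fdr(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg adjusted p-values and rejection flags."""
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj
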