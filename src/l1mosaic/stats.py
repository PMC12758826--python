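"""Shared statistical primitives.

Implemented from their definitions so that the conventions the pipeline
depends on are explicit and under our control:

* Box-Cox power transform with an additive offset (reporter-cell counts
  contain zeros).
* One-way ANOVA from between/within sums of squares.
* Two-sample t (pooled variance by default, Welch optional).
* Fisher's exact test from the hypergeometric distribution, with the
  *sample* odds ratio ``(a*d)/(b*c)`` — reported as ``+inf`` when the
  denominator is zero and the numerator is not, and NaN when both vanish.
* Benjamini-Hochberg step-up adjustment.

Distribution tail areas (normal, t, F) come from ``scipy``; the
hypergeometric pmf is evaluated via log-gamma for numerical stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special
from scipy import stats as _spstats

__all__ = [
    "BoxCoxParams",
    "boxcox",
    "inv_boxcox",
    "bh_adjust",
    "hypergeom_logpmf",
    "sample_odds_ratio",
    "fisher_exact",
    "FisherResult",
    "anova_oneway",
    "AnovaResult",
    "t_two_sample",
    "TTestResult",
]

# Relative tolerance when comparing point masses for the two-sided Fisher
# p-value; guards against ties lost to floating-point rounding.
_PMF_RELTOL = 1e-7


@dataclass(frozen=True)
class BoxCoxParams:
    """Box-Cox transform parameters.

    lambda_ is the power; 0.041 is the value used for reporter-cell
    counts in this pipeline. ``offset`` is added before transforming so
    zero counts remain in the domain.
    """

    lambda_: float = 0.041
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


def boxcox(x, params: BoxCoxParams | None = None):
    """Box-Cox transform ``((x+offset)**lambda - 1)/lambda`` (log at lambda=0).

    Strictly increasing in ``x``; raises if any shifted value is <= 0.
    """
    p = params or BoxCoxParams()
    x = np.asarray(x, dtype=float)
    shifted = x + p.offset
    if np.any(shifted <= 0):
        raise ValueError("Box-Cox requires x + offset > 0 for every value")
    if p.lambda_ == 0:
        out = np.log(shifted)
    else:
        # expm1 form stays accurate (and monotone) for tiny |lambda|
        out = np.expm1(p.lambda_ * np.log(shifted)) / p.lambda_
    return out if out.ndim else float(out)


def inv_boxcox(y, params: BoxCoxParams | None = None):
    """Inverse of :func:`boxcox` (returns the original ``x``)."""
    p = params or BoxCoxParams()
    y = np.asarray(y, dtype=float)
    if p.lambda_ == 0:
        shifted = np.exp(y)
    else:
        shifted = np.exp(np.log1p(y * p.lambda_) / p.lambda_)
    out = shifted - p.offset
    return out if out.ndim else float(out)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving with the input; monotonicity enforced by the
    cumulative minimum over the sorted sequence. Values must lie in [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def hypergeom_logpmf(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(A = a) for the 2x2 table with margins (row1, row2, col1).

    A is the top-left cell; the distribution conditions on all margins.
    Evaluated via log-gamma: log C(row1, a) + log C(row2, col1-a)
    - log C(N, col1).
    """
    c = col1 - a
    if a < 0 or c < 0 or a > row1 or c > row2:
        return -np.inf
    n_total = row1 + row2

    def _logcomb(n: int, k: int) -> float:
        return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)

    return _logcomb(row1, a) + _logcomb(row2, c) - _logcomb(n_total, col1)


def _hypergeom_logpmf_vector(a: np.ndarray, row1: int, row2: int, col1: int) -> np.ndarray:
    """Vectorized log pmf over a support array (all entries feasible)."""
    a = np.asarray(a, dtype=float)
    c = col1 - a
    n_total = row1 + row2

    def _logcomb(n, k):
        return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)

    return _logcomb(row1, a) + _logcomb(row2, c) - _logcomb(n_total, col1)


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Unconditioned sample odds ratio (a*d)/(b*c).

    ``+inf`` when b*c == 0 with a*d > 0; NaN when both products are zero
    (the ratio is undefined).
    """
    num = a * d
    den = b * c
    if den == 0:
        if num == 0:
            return float("nan")
        return float("inf")
    return num / den


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    pvalue: float


def fisher_exact(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> FisherResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric point masses over the feasible
    support: for ``two-sided`` all tables at most as probable as the
    observed one (with a small relative tolerance for float ties), for
    ``greater``/``less`` the corresponding tail of A = a.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or int(v) != v:
            raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    row1, row2, col1 = a + b, c + d, a + c
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    if lo > hi:  # empty support: degenerate margins
        return FisherResult(sample_odds_ratio(a, b, c, d), 1.0)
    support = np.arange(lo, hi + 1)
    logpmf = _hypergeom_logpmf_vector(support, row1, row2, col1)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    p_obs = pmf[a - lo]
    if alternative == "two-sided":
        p = float(pmf[pmf <= p_obs * (1 + _PMF_RELTOL)].sum())
    elif alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return FisherResult(sample_odds_ratio(a, b, c, d), min(p, 1.0))


# ---------------------------------------------------------------------------
# ANOVA and t-tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    pvalue: float


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from between/within sums of squares.

    Each group needs n >= 2. When both between- and within-group
    variation are exactly zero (all observations identical), F is
    defined as 0 with p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    n_total = sum(g.size for g in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df_between, df_within, 1.0)
        return AnovaResult(float("inf"), df_between, df_within, 0.0)
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(_spstats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(float(f_stat), df_between, df_within, p)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    pvalue: float


def t_two_sample(a: Sequence[float], b: Sequence[float], welch: bool = False) -> TTestResult:
    """Two-sample t-test, pooled variance by default, Welch optional.

    Two-sided p-value. Degenerate case of zero variance in both groups
    with equal means gives t = 0, p = 1.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    diff = x.mean() - y.mean()
    if welch:
        se2 = vx / nx + vy / ny
        if se2 == 0:
            return _degenerate_t(diff, nx + ny - 2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        t_stat = diff / math.sqrt(se2)
    else:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        if sp2 == 0:
            return _degenerate_t(diff, df)
        t_stat = diff / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = float(2 * _spstats.t.sf(abs(t_stat), df))
    return TTestResult(float(t_stat), float(df), min(p, 1.0))


def _degenerate_t(diff: float, df: float) -> TTestResult:
    if diff == 0:
        return TTestResult(0.0, float(df), 1.0)
    return TTestResult(math.copysign(float("inf"), diff), float(df), 0.0)
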