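"""Statistical primitives: correlations, rank-sum test, hypergeometric
gene-set enrichment.

Exact permutation p-values are used wherever the permutation space is small
enough to enumerate (correlations up to ``exact_n`` observations, rank-sum
up to ~2·10⁵ group assignments); asymptotic approximations from scipy take
over beyond that.  Ties are handled by midranks throughout.  Degenerate
inputs (zero variance) yield NaN results flagged as undefined rather than
exceptions, so scans over many fixtures never abort on one flat series.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

_EPS = 1e-12
#: largest permutation count enumerated exactly for the rank-sum test
_MAX_ENUM = 200_000


@dataclass
class CorrelationResult:
    statistic: float
    p_value: float
    undefined: bool = False

    def __iter__(self):
        return iter((self.statistic, self.p_value))


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return math.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _permutation_p(
    x: np.ndarray, y: np.ndarray, r_obs: float, alternative: str
) -> float:
    """Exact permutation p over all n! orderings of y, evaluated in
    vectorised chunks (r is linear in the permuted y once centred)."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    count = 0
    total = 0
    chunk_size = 40_000
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, chunk_size))
        if not chunk:
            break
        idx = np.array(chunk)
        rs = (yc[idx] @ xc) / denom
        total += len(rs)
        if alternative == "two-sided":
            count += int((np.abs(rs) >= abs(r_obs) - _EPS).sum())
        elif alternative == "greater":
            count += int((rs >= r_obs - _EPS).sum())
        else:
            count += int((rs <= r_obs + _EPS).sum())
    return count / total


def pearson(
    x, y, alternative: str = "two-sided", exact_n: int = 8
) -> CorrelationResult:
    """Pearson correlation with exact permutation p for small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 observations")
    r = _pearson_r(x, y)
    if math.isnan(r):
        return CorrelationResult(math.nan, math.nan, undefined=True)
    if len(x) <= exact_n:
        p = _permutation_p(x, y, r, alternative)
    else:
        p = float(sps.pearsonr(x, y, alternative=alternative).pvalue)
    return CorrelationResult(r, p)


def spearman(
    x, y, alternative: str = "two-sided", exact_n: int = 8
) -> CorrelationResult:
    """Spearman rank correlation (midranks), permutation-exact for small n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _pearson_r(rx, ry)
    if math.isnan(rho):
        return CorrelationResult(math.nan, math.nan, undefined=True)
    if len(x) <= exact_n:
        p = _permutation_p(rx, ry, rho, alternative)
    else:
        p = float(sps.spearmanr(x, y, alternative=alternative).pvalue)
    return CorrelationResult(rho, p)


def wilcoxon_ranksum(
    a, b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney/Wilcoxon rank-sum test; returns (U statistic, p).

    ``alternative='less'`` tests whether ``a`` tends to be smaller than
    ``b``.  The p-value is computed by exhaustive enumeration of all group
    assignments when their number is small enough, with midranks so ties
    are handled identically in the observed and permuted statistics;
    otherwise scipy's normal approximation with tie correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:na].sum())
    u1 = r1 - na * (na + 1) / 2.0
    if comb(na + nb, na) <= _MAX_ENUM:
        n = na + nb
        ge = le = total = 0
        for idx in itertools.combinations(range(n), na):
            r_perm = float(ranks[list(idx)].sum())
            total += 1
            if r_perm >= r1 - _EPS:
                ge += 1
            if r_perm <= r1 + _EPS:
                le += 1
        p_greater = ge / total
        p_less = le / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        p = float(sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic").pvalue)
    return u1, p


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric enrichment of an annotated set in a draw."""

    universe_size: int  # N
    annotated_size: int  # K
    drawn_size: int  # n
    overlap: int  # k
    p_value: float

    def __post_init__(self):
        assert self.overlap <= min(self.annotated_size, self.drawn_size)
        assert 0.0 <= self.p_value <= 1.0 + _EPS


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log-space."""
    lo = max(0, n + K - N)
    hi = min(K, n)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    js = np.arange(k, hi + 1)
    return float(np.exp(logsumexp(sps.hypergeom.logpmf(js, N, K, n))))


def hypergeometric_enrichment(
    upregulated: set, annotated: set, universe: set
) -> EnrichmentResult:
    """Enrichment of an annotated gene set among upregulated genes.

    Models the upregulated genes as a draw of n from the universe of N genes
    containing K annotated ones and reports the upper-tail probability of
    observing at least the actual overlap k.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    upregulated = set(upregulated)
    annotated = set(annotated)
    if not upregulated <= universe:
        raise ValueError("upregulated set is not a subset of the universe")
    if not annotated <= universe:
        raise ValueError("annotated set is not a subset of the universe")
    N, K, n = len(universe), len(annotated), len(upregulated)
    k = len(upregulated & annotated)
    return EnrichmentResult(N, K, n, k, hypergeometric_upper_tail(N, K, n, k))
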