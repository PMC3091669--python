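"""Binomial statistics for allele-specific expression.

The model: at a heterozygous site, each informative read is an independent
Bernoulli trial in which the reference (B6) allele is observed with null
probability ``p0`` — 0.5 in an F1, the pooled genotype frequency of the
reference allele in an F2 pool.  Departure from p0 in the read counts is
evidence of allele-specific expression (ASE).

Conventions
-----------
* ``binomial_tail_p`` returns the *smaller single tail*,
  min(P(X <= k), P(X >= k)); it is never doubled.  A doubled two-sided
  variant is available via ``doubled=True``.
* ``lbp`` is the signed score -log10(p) with the sign set *negative* when
  the bias is toward the B6/reference allele (k/n > p0), positive toward the
  alternative strain, and exactly zero when k/n == p0.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import GeneASE, PoolSpec, PowerQuery

__all__ = [
    "binomial_tail_p", "lbp", "gene_ase", "ci_envelope",
    "replicate_error_analysis", "concordance", "excess_ase_fraction",
    "power", "detectable_fold",
]


def _validate_kn(k, n, p0) -> None:
    k = np.asarray(k)
    n = np.asarray(n)
    p0 = np.asarray(p0)
    if np.any(n < 1):
        raise ValueError("no informative reads (n = 0)")
    if np.any((k < 0) | (k > n)):
        raise ValueError("require 0 <= k <= n")
    if np.any((p0 <= 0.0) | (p0 >= 1.0)):
        raise ValueError("p0 must lie strictly inside (0, 1)")


def binomial_tail_p(k, n, p0=0.5, doubled: bool = False):
    """Smaller cumulative tail of Binomial(n, p0) at k.

    Parameters accept scalars or arrays (broadcast).  With ``doubled=True``
    the value is min(1, 2 * min-tail), the conventional two-sided exact
    binomial p.
    """
    _validate_kn(k, n, p0)
    lower = sps.binom.cdf(k, n, p0)
    upper = sps.binom.sf(np.asarray(k) - 1, n, p0)
    p = np.minimum(lower, upper)
    if doubled:
        p = np.minimum(1.0, 2.0 * p)
    p = np.minimum(p, 1.0)
    if np.ndim(p) == 0:
        return float(p)
    return p


def lbp(k, n, p0=0.5):
    """Signed log10 binomial score: negative = B6/reference-biased.

    Zero exactly when the observed ratio equals the null (no defined
    direction).
    """
    p = binomial_tail_p(k, n, p0)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    ratio = k / n
    sign = np.where(ratio > p0, -1.0, np.where(ratio < p0, 1.0, 0.0))
    val = sign * (-np.log10(p))
    if np.ndim(val) == 0:
        return float(val)
    return val


def gene_ase(gene_id: str, total_ref: int, total_alt: int, p0: float,
             n_snps_informative: int = 0, n_snps_agreeing: int = 0) -> GeneASE:
    """Gene-level binomial ASE statistic from aggregated allele counts."""
    if not (0.0 < p0 < 1.0):
        raise ValueError("monomorphic pool: p0 must lie strictly inside (0, 1)")
    n = total_ref + total_alt
    p = binomial_tail_p(total_ref, n, p0)
    score = lbp(total_ref, n, p0)
    return GeneASE(
        gene_id=gene_id, total_ref=total_ref, total_alt=total_alt,
        n_snps_informative=n_snps_informative,
        n_snps_agreeing=n_snps_agreeing,
        p0=p0, binomial_p=p, lbp=score,
    )


def ci_envelope(n, alpha: float = 0.01):
    """Maximal |ref - alt| read difference inside the (1 - alpha) null region.

    For each coverage n the retention set is grown symmetrically about n/2
    (in order of increasing |2k - n|) until it holds at least 1 - alpha of
    the Binomial(n, 0.5) mass; the returned envelope d(n) is the largest
    |2k - n| retained.  Points with |ref - alt| > d(n) fall outside the
    (1 - alpha) confidence band.  Vectorized over n for plotting.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    ns = np.atleast_1d(np.asarray(n, dtype=int))
    if np.any(ns < 1):
        raise ValueError("n must be >= 1")
    out = np.empty(ns.shape, dtype=int)
    for i, ni in enumerate(ns.ravel()):
        k = np.arange(ni + 1)
        d = np.abs(2 * k - ni)
        order = np.argsort(d, kind="stable")
        cum = np.cumsum(sps.binom.pmf(k[order], ni, 0.5))
        stop = int(np.searchsorted(cum, 1.0 - alpha - 1e-12))
        stop = min(stop, ni)
        out.ravel()[i] = d[order][stop]
    if np.ndim(n) == 0:
        return int(out.ravel()[0])
    return out


def replicate_error_analysis(counts_rep1: pd.DataFrame,
                             counts_rep2: pd.DataFrame,
                             seed: int,
                             pseudocount: float = 0.5):
    """Observed vs binomial-expected error between two replicate libraries.

    Each replicate is a frame with columns ``snp_id, ref_count, alt_count``.
    For every shared SNP the observed error is
    |log2(ref1/alt1) - log2(ref2/alt2)| (Haldane-Anscombe pseudocount on
    zero cells).  A simulated twin is built by drawing, per SNP, two
    binomial counts at the replicate depths from the pooled allelic ratio,
    and the two error distributions are compared with the Wilcoxon rank-sum
    test.

    Returns ``(frame, rank_sum_p)`` where the frame has one row per shared
    SNP with observed and simulated errors and the mean read count.
    """
    merged = counts_rep1.merge(counts_rep2, on="snp_id", suffixes=("_1", "_2"))
    if len(merged) < 2:
        raise ValueError("need at least 2 shared SNPs across replicates")
    rng = np.random.default_rng(seed)

    r1, a1 = merged.ref_count_1.to_numpy(float), merged.alt_count_1.to_numpy(float)
    r2, a2 = merged.ref_count_2.to_numpy(float), merged.alt_count_2.to_numpy(float)

    def log_ratio(r, a):
        zero = (r == 0) | (a == 0)
        rr = np.where(zero, r + pseudocount, r)
        aa = np.where(zero, a + pseudocount, a)
        return np.log2(rr / aa)

    observed = np.abs(log_ratio(r1, a1) - log_ratio(r2, a2))

    n1 = (r1 + a1).astype(int)
    n2 = (r2 + a2).astype(int)
    pooled = (r1 + r2) / np.maximum(n1 + n2, 1)
    pooled = np.clip(pooled, 1e-9, 1 - 1e-9)
    s1 = rng.binomial(n1, pooled)
    s2 = rng.binomial(n2, pooled)
    simulated = np.abs(log_ratio(s1.astype(float), (n1 - s1).astype(float))
                       - log_ratio(s2.astype(float), (n2 - s2).astype(float)))

    stat, p = sps.ranksums(observed, simulated)
    frame = pd.DataFrame({
        "snp_id": merged.snp_id,
        "mean_reads": (n1 + n2) / 2.0,
        "observed_error": observed,
        "simulated_error": simulated,
    })
    return frame, float(p)


def concordance(x, y):
    """Squared Pearson correlation with its p-value: returns (R2, n, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    if len(x) < 3:
        raise ValueError("need n >= 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    res = sps.pearsonr(x, y)
    return float(res.statistic ** 2), len(x), float(res.pvalue)


def _null_pvalue_grid(n: int, p0: float):
    """Achievable min-tail p-values of Binomial(n, p0) with their null mass,
    sorted ascending, as (p_sorted, cum_mass)."""
    k = np.arange(n + 1)
    p = np.minimum(sps.binom.cdf(k, n, p0), sps.binom.sf(k - 1, n, p0))
    pmf = sps.binom.pmf(k, n, p0)
    order = np.argsort(p, kind="stable")
    return p[order], np.cumsum(pmf[order])


def excess_ase_fraction(snp_table: pd.DataFrame):
    """Fraction of SNPs with more allele-specificity than the binomial null.

    ``snp_table`` has columns ``k`` (reference reads), ``n`` (total reads)
    and ``p0`` (per-locus null fraction).  Each SNP's min-tail p is compared
    against the exact null distribution of achievable p-values at its own
    (n, p0); the excess fraction is the largest gap
    observed-CDF(t) - expected-CDF(t) over the achievable p-value grid.

    Returns ``(excess, threshold)`` — the maximal gap and the p-value at
    which it is attained.
    """
    if len(snp_table) == 0:
        raise ValueError("empty SNP table")
    k = snp_table["k"].to_numpy(int)
    n = snp_table["n"].to_numpy(int)
    p0 = snp_table["p0"].to_numpy(float)
    _validate_kn(k, n, p0)

    observed_p = np.minimum(sps.binom.cdf(k, n, p0), sps.binom.sf(k - 1, n, p0))
    grid = np.unique(observed_p)

    # expected CDF at each grid point, averaged over the per-SNP exact nulls;
    # cache by (n, p0) since loci share coverage and pool composition
    expected = np.zeros_like(grid)
    cache: dict[tuple[int, float], tuple[np.ndarray, np.ndarray]] = {}
    keys = [(int(ni), round(float(pi), 9)) for ni, pi in zip(n, p0)]
    counts: dict[tuple[int, float], int] = {}
    for key in keys:
        counts[key] = counts.get(key, 0) + 1
    for key, mult in counts.items():
        if key not in cache:
            cache[key] = _null_pvalue_grid(*key)
        p_sorted, cum = cache[key]
        idx = np.searchsorted(p_sorted, grid, side="right") - 1
        contrib = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
        expected += mult * contrib
    expected /= len(snp_table)

    obs_cdf = np.searchsorted(np.sort(observed_p), grid, side="right") / len(snp_table)
    gap = obs_cdf - expected
    i = int(np.argmax(gap))
    return float(max(gap[i], 0.0)), float(grid[i])


def _critical_value(n: int, p0: float, alpha: float) -> int:
    """Smallest c with P(X >= c | n, p0) <= alpha; n + 1 if unattainable."""
    k = np.arange(n + 2)
    sf = sps.binom.sf(k - 1, n, p0)
    ok = np.nonzero(sf <= alpha)[0]
    return int(ok[0]) if len(ok) else n + 1


def power(query: PowerQuery | None = None, *, n: int | None = None,
          fold: float | None = None, alpha: float = 0.05,
          tails: str = "one", p0: float = 0.5) -> float:
    """Exact power of the binomial ASE test at coverage n against a fold.

    One-tailed: reject when X >= c, with c the smallest count whose upper
    tail under the null is <= alpha.  Two-tailed: alpha/2 per side, rejecting
    high or low.  The alternative puts the over-expressed allele at
    probability fold/(fold+1) (scaled by p0 when the pool is unbalanced).
    """
    if query is None:
        query = PowerQuery(n=n, fold=fold, alpha=alpha, tails=tails)
    n, fold, alpha, tails = query.n, query.fold, query.alpha, query.tails
    p1 = p0 * fold / (p0 * fold + (1 - p0))
    if tails == "one":
        c = _critical_value(n, p0, alpha)
        if c > n:
            return 0.0
        return float(sps.binom.sf(c - 1, n, p1))
    c_hi = _critical_value(n, p0, alpha / 2.0)
    # symmetric lower critical value
    k = np.arange(n + 1)
    cdf = sps.binom.cdf(k, n, p0)
    lo_ok = np.nonzero(cdf <= alpha / 2.0)[0]
    c_lo = int(lo_ok[-1]) if len(lo_ok) else -1
    pw = 0.0
    if c_hi <= n:
        pw += float(sps.binom.sf(c_hi - 1, n, p1))
    if c_lo >= 0:
        pw += float(sps.binom.cdf(c_lo, n, p1))
    return pw


def detectable_fold(n: int, alpha: float = 0.05, target_power: float = 0.5,
                    tails: str = "one", tol: float = 1e-6) -> float:
    """Smallest allelic fold difference detectable with the given power.

    Inverts :func:`power` by bisection on fold; power is non-decreasing in
    fold.
    """
    lo, hi = 1.0, 2.0
    while power(PowerQuery(n=n, fold=hi, alpha=alpha, tails=tails)) < target_power:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("target power unattainable at this coverage")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if power(PowerQuery(n=n, fold=mid, alpha=alpha, tails=tails)) >= target_power:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return hi
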