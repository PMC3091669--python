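"""Minimal single-marker cis-eQTL stage.

Each gene is tested only at its own locus with an additive genotype coding
(-1, 0, +1 for 0/1/2 BTBR alleles): *cis*-acting variants are expected to
behave additively, so no dominance term is fitted and no genome-wide scan
is performed.  LOD = (n/2) * log10(RSS_null / RSS_fit); the additive effect
is the regression slope, which under a balanced design equals half the
difference between homozygote class means, positive when BTBR homozygotes
express higher.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .types import EqtlResult, SnpRecord

_RSS_EPS = 1e-12

P0_CLAMP = (0.01, 0.99)


def marker_regression(expression, genotype, gene_id: str = "") -> EqtlResult:
    """Additive single-marker regression of expression on genotype.

    ``genotype`` codes count BTBR alleles (0/1/2); ``expression`` is the
    per-animal trait in the same order.
    """
    y = np.asarray(expression, dtype=float)
    g = np.asarray(genotype, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("expression and genotype must be same-length vectors")
    if np.any(~np.isin(g, (0.0, 1.0, 2.0))):
        raise ValueError("genotype codes must be 0/1/2 (no missing values)")
    n = len(y)
    x = g - 1.0
    y_c = y - y.mean()
    x_c = x - x.mean()
    sxx = float(x_c @ x_c)
    rss_null = float(y_c @ y_c)
    if rss_null == 0.0 or sxx == 0.0:
        return EqtlResult(gene_id=gene_id, lod=0.0, additive_effect=0.0)
    beta = float(x_c @ y_c) / sxx
    resid = y_c - beta * x_c
    rss_fit = float(resid @ resid)
    rss_fit = max(rss_fit, _RSS_EPS * rss_null)
    lod = (n / 2.0) * np.log10(rss_null / rss_fit)
    return EqtlResult(gene_id=gene_id, lod=max(lod, 0.0), additive_effect=beta)


def marker_regression_table(expression: pd.DataFrame,
                            genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene regression at the gene's own locus.

    ``expression`` is genes x animals; ``genotypes`` is loci x animals with
    the same animal columns and an index of locus ids matching the gene
    index (one locus per gene).
    """
    common = expression.index.intersection(genotypes.index)
    rows = []
    for gid in common:
        res = marker_regression(expression.loc[gid].to_numpy(),
                                genotypes.loc[gid].to_numpy(), gene_id=str(gid))
        rows.append({"gene_id": res.gene_id, "lod": res.lod,
                     "additive_effect": res.additive_effect})
    return pd.DataFrame(rows)


def call_cis(results: pd.DataFrame, lod_threshold: float = 3.0,
             effect_threshold: float = 0.0,
             excluded_genes: set | frozenset = frozenset()) -> pd.DataFrame:
    """Genes passing the LOD and |additive effect| thresholds, minus any
    probe-SNP-excluded genes."""
    mask = (results["lod"] > lod_threshold) \
        & (results["additive_effect"].abs() > effect_threshold) \
        & ~results["gene_id"].isin(excluded_genes)
    return results[mask].reset_index(drop=True)


def flag_probe_snp_overlap(probes: pd.DataFrame,
                           snps: Sequence[SnpRecord]) -> set[str]:
    """Genes whose microarray probes contain a SNP (half-open intervals).

    Probes with a strain-distinguishing SNP inside the probe sequence
    produce artifactual hybridization differences and are removed from the
    eQTL comparison.  ``probes`` has columns gene_id, chrom, start, end with
    0-based half-open coordinates.
    """
    excluded: set[str] = set()
    by_chrom: dict[str, list[int]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s.pos - 1)  # 0-based
    for chrom in by_chrom:
        by_chrom[chrom] = sorted(by_chrom[chrom])
    for row in probes.itertuples(index=False):
        positions = by_chrom.get(row.chrom)
        if not positions:
            continue
        i = np.searchsorted(positions, row.start, side="left")
        if i < len(positions) and positions[i] < row.end:
            excluded.add(str(row.gene_id))
    return excluded


def pool_null_fraction(codes) -> float:
    """Reference(B6)-allele fraction expected in a pooled RNA sample.

    ``codes`` are the pooled animals' genotype codes at the locus (count of
    BTBR alleles).  Clamped away from 0/1 with a warning: a monomorphic
    pool cannot support ASE testing.
    """
    codes = np.asarray(codes, dtype=float)
    if codes.size == 0:
        raise ValueError("empty pool")
    p0 = 1.0 - codes.sum() / (2.0 * codes.size)
    lo, hi = P0_CLAMP
    if p0 < lo or p0 > hi:
        warnings.warn(f"pool null fraction {p0:.4f} clamped to [{lo}, {hi}]"
                      " (near-monomorphic locus)")
        p0 = min(max(p0, lo), hi)
    return float(p0)
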