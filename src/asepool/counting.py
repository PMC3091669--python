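"""Filtered per-SNP allele counting and gene-level aggregation.

Reads overlapping a strain-distinguishing SNP are tallied as reference
(B6) or alternative (BTBR/CAST) by the observed base.  Filters applied
before counting:

* non-unique alignments dropped (``require_unique``);
* error-prone SNP classes (ordered C/A, A/C, G/T pairs) dropped
  (``exclude_snp_types``);
* sites whose mean base quality across contributing reads — both strands,
  computed before the strand split — falls below ``min_mean_quality``
  dropped.

Bases matching neither allele are discarded and tallied in a mismatch
counter; observations at positions absent from the SNP table are skipped
and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import observations_to_frame
from .types import (
    AlleleCount,
    FilterConfig,
    GeneModel,
    ReadObservation,
    SnpRecord,
)

#: Rejection reasons emitted by gene aggregation.
REJECT_MIN_SNPS = "min_snps"
REJECT_MIN_READS = "min_reads"
REJECT_MAJORITY = "majority_disagreement"
REJECT_NO_SNPS = "no_informative_snps"
ACCEPTED = "ok"


@dataclass(frozen=True)
class CountResult:
    """Per-SNP strand-resolved counts plus filter accounting."""

    counts: pd.DataFrame  # chrom pos strand ref_allele alt_allele ref_count alt_count mean_quality
    n_mismatch: int  # bases matching neither allele
    n_unknown_position: int  # observations with no SNP at their position

    def to_records(self) -> list[AlleleCount]:
        return [
            AlleleCount(r.chrom, int(r.pos), r.strand, int(r.ref_count),
                        int(r.alt_count), float(r.mean_quality))
            for r in self.counts.itertuples(index=False)
        ]


_COUNT_COLUMNS = ["chrom", "pos", "strand", "ref_allele", "alt_allele",
                  "ref_count", "alt_count", "mean_quality"]


def count_alleles(observations: Sequence[ReadObservation] | pd.DataFrame,
                  snps: Sequence[SnpRecord],
                  config: FilterConfig = FilterConfig()) -> CountResult:
    """Tally filtered reference/alternative reads per (SNP, strand)."""
    if isinstance(observations, pd.DataFrame):
        obs = observations.copy()
    else:
        obs = observations_to_frame(observations)
    empty = pd.DataFrame(columns=_COUNT_COLUMNS)
    if len(obs) == 0:
        return CountResult(empty, 0, 0)

    snp_frame = pd.DataFrame({
        "chrom": [s.chrom for s in snps],
        "pos": [s.pos for s in snps],
        "ref_allele": [s.ref_allele for s in snps],
        "alt_allele": [s.alt_allele for s in snps],
        "excluded_type": [s.excluded_type for s in snps],
    })

    if config.require_unique:
        obs = obs[obs["unique"].astype(bool)]

    merged = obs.merge(snp_frame, on=["chrom", "pos"], how="left")
    unknown = merged["ref_allele"].isna()
    n_unknown = int(unknown.sum())
    merged = merged[~unknown]

    if config.exclude_snp_types:
        merged = merged[~merged["excluded_type"].astype(bool)]

    if len(merged) == 0:
        return CountResult(empty, 0, n_unknown)

    is_ref = merged["base"] == merged["ref_allele"]
    is_alt = merged["base"] == merged["alt_allele"]
    n_mismatch = int((~(is_ref | is_alt)).sum())
    merged = merged.assign(is_ref=is_ref, is_alt=is_alt)
    merged = merged[is_ref | is_alt]
    if len(merged) == 0:
        return CountResult(empty, n_mismatch, n_unknown)

    # site-level mean quality over contributing reads on both strands
    site_q = merged.groupby(["chrom", "pos"])["qual"].mean().rename("site_mean_q")
    merged = merged.merge(site_q.reset_index(), on=["chrom", "pos"])
    merged = merged[merged["site_mean_q"] >= config.min_mean_quality]
    if len(merged) == 0:
        return CountResult(empty, n_mismatch, n_unknown)

    grouped = merged.groupby(["chrom", "pos", "strand"], sort=True).agg(
        ref_allele=("ref_allele", "first"),
        alt_allele=("alt_allele", "first"),
        ref_count=("is_ref", "sum"),
        alt_count=("is_alt", "sum"),
        mean_quality=("qual", "mean"),
    ).reset_index()
    grouped["ref_count"] = grouped["ref_count"].astype(int)
    grouped["alt_count"] = grouped["alt_count"].astype(int)
    return CountResult(grouped[_COUNT_COLUMNS], n_mismatch, n_unknown)


def _direction_vote(ref_count: np.ndarray, alt_count: np.ndarray,
                    p0: np.ndarray) -> np.ndarray:
    """Per-SNP strain-bias vote: +1 reference-biased, -1 alternative-biased,
    0 abstain (exact null ratio)."""
    score = ref_count * (1.0 - p0) - alt_count * p0
    return np.sign(score)


def aggregate_to_gene(counts: CountResult | pd.DataFrame,
                      gene_models: Sequence[GeneModel],
                      p0: float | pd.Series = 0.5,
                      min_reads: int = 10,
                      min_snps: int = 3) -> pd.DataFrame:
    """Sum per-SNP counts to genes with eligibility screening.

    Only counts on the gene's annotated strand and within the transcript
    span (introns included) contribute.  A gene is accepted when it has at
    least ``min_snps`` informative SNPs, at least ``min_reads`` summed count
    units, and strictly more than half of its non-abstaining SNPs agree on
    the direction of strain bias.  Rejected genes are emitted with a
    ``status`` naming the failed rule.  A SNP inside two overlapping
    same-strand genes contributes to both (``shared_snps`` flags this).

    ``p0`` may be a scalar (F1 mode) or a Series indexed like the gene ids
    giving each gene's locus null fraction.

    Returns one row per gene: gene_id, total_ref, total_alt,
    n_snps_informative, n_snps_agreeing, p0, status, shared_snps.
    """
    frame = counts.counts if isinstance(counts, CountResult) else counts
    rows = []
    # occupancy by (chrom,pos) across genes to flag shared SNPs
    snp_claims: dict[tuple[str, int], int] = {}
    per_gene_sites: dict[str, set[tuple[str, int]]] = {}

    for gm in gene_models:
        sub = frame[(frame["chrom"] == gm.chrom)
                    & (frame["strand"] == gm.strand)
                    & (frame["pos"] - 1 >= gm.start)
                    & (frame["pos"] - 1 < gm.end)]
        sites = set(zip(sub["chrom"], sub["pos"]))
        per_gene_sites[gm.gene_id] = sites
        for s in sites:
            snp_claims[s] = snp_claims.get(s, 0) + 1

        gene_p0 = float(p0[gm.gene_id]) if isinstance(p0, pd.Series) else float(p0)
        informative = sub[(sub["ref_count"] + sub["alt_count"]) > 0]
        n_snps = informative["pos"].nunique()
        total_ref = int(informative["ref_count"].sum())
        total_alt = int(informative["alt_count"].sum())
        total = total_ref + total_alt

        if n_snps == 0:
            status, n_agree = REJECT_NO_SNPS, 0
        else:
            per_site = informative.groupby("pos").agg(
                ref_count=("ref_count", "sum"), alt_count=("alt_count", "sum"))
            votes = _direction_vote(per_site["ref_count"].to_numpy(float),
                                    per_site["alt_count"].to_numpy(float),
                                    np.full(len(per_site), gene_p0))
            voting = votes[votes != 0]
            if len(voting) == 0:
                majority_ok, n_agree = True, 0
            else:
                n_pos = int((voting > 0).sum())
                n_neg = int((voting < 0).sum())
                n_agree = max(n_pos, n_neg)
                majority_ok = n_agree * 2 > len(voting)
            if n_snps < min_snps:
                status = REJECT_MIN_SNPS
            elif total < min_reads:
                status = REJECT_MIN_READS
            elif not majority_ok:
                status = REJECT_MAJORITY
            else:
                status = ACCEPTED
        rows.append({
            "gene_id": gm.gene_id, "total_ref": total_ref,
            "total_alt": total_alt, "n_snps_informative": int(n_snps),
            "n_snps_agreeing": int(n_agree), "p0": gene_p0, "status": status,
        })

    out = pd.DataFrame(rows)
    if len(out):
        out["shared_snps"] = [
            any(snp_claims[s] > 1 for s in per_gene_sites[g]) if per_gene_sites[g] else False
            for g in out["gene_id"]
        ]
    return out
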