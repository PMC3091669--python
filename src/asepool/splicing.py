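"""Candidate allele-specific splicing from junction-spanning reads.

A read that spans an alternative splice junction *and* covers a SNP reports
both the isoform (exon included vs skipped) and the allele of origin.  When
both isoforms are represented at a site, a shift in allelic ratio between
isoforms suggests allele-specific splicing.  To avoid conflating this with
plain transcription-level ASE, the statistic is a *bound*: the one-sided
exact binomial tail (at p0 = 0.5) of the allele split of the isoform with
fewer total reads, taken in the direction of its observed bias.  The true
joint probability of allele-specific splicing is no larger.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import observations_to_frame
from .stats import binomial_tail_p
from .types import GeneModel, ReadObservation, SnpRecord, SplicingEvent

__all__ = ["junction_allele_table", "splicing_ase_bound"]


def splicing_ase_bound(inc_ref: int, inc_alt: int,
                       skip_ref: int, skip_alt: int) -> tuple[float, str, bool]:
    """Minor-isoform binomial bound on allele-specific splicing evidence.

    The minor isoform is the one with strictly fewer total reads; on a tie
    the more allelically balanced isoform is used and the event is flagged.
    Returns ``(p_bound, minor_isoform, tie)``.
    """
    n_inc = inc_ref + inc_alt
    n_skip = skip_ref + skip_alt
    if n_inc < 1 or n_skip < 1:
        raise ValueError("both isoforms must have at least one read")
    tie = n_inc == n_skip
    if n_inc < n_skip:
        minor = "included"
    elif n_skip < n_inc:
        minor = "skipped"
    else:
        # tie: the more balanced isoform (smaller |ref - alt|)
        minor = "included" if abs(inc_ref - inc_alt) <= abs(skip_ref - skip_alt) \
            else "skipped"
    k, n = (inc_ref, n_inc) if minor == "included" else (skip_ref, n_skip)
    p = binomial_tail_p(k, n, 0.5)
    return float(p), minor, tie


def junction_allele_table(observations: Sequence[ReadObservation] | pd.DataFrame,
                          snps: Sequence[SnpRecord],
                          gene_models: Sequence[GeneModel]) -> list[SplicingEvent]:
    """Per-junction included/skipped allele tables with the binomial bound.

    Only junction-labeled observations in the same orientation as their
    gene's transcript contribute; an event is emitted only when both
    isoforms have at least one allele-informative read.  Junctions that fall
    in no gene model are skipped.
    """
    obs = observations if isinstance(observations, pd.DataFrame) \
        else observations_to_frame(observations)
    obs = obs[obs["junction_id"].notna() & obs["isoform"].notna()]
    if len(obs) == 0:
        return []

    allele_map = {(s.chrom, s.pos): (s.ref_allele, s.alt_allele) for s in snps}

    events: dict[tuple[str, str], dict[str, int]] = {}
    for row in obs.itertuples(index=False):
        alleles = allele_map.get((row.chrom, row.pos))
        if alleles is None:
            continue
        gene = next((g for g in gene_models
                     if g.chrom == row.chrom and g.contains(row.pos)), None)
        if gene is None:
            continue
        if row.strand != gene.strand:
            continue  # antisense-orientation reads do not report splicing
        ref, alt = alleles
        if row.base == ref:
            which = "ref"
        elif row.base == alt:
            which = "alt"
        else:
            continue
        key = (gene.gene_id, str(row.junction_id))
        cell = f"{row.isoform}_{which}"
        events.setdefault(key, {"included_ref": 0, "included_alt": 0,
                                "skipped_ref": 0, "skipped_alt": 0})
        events[key][cell] += 1

    out = []
    for (gene_id, junction_id), c in sorted(events.items()):
        n_inc = c["included_ref"] + c["included_alt"]
        n_skip = c["skipped_ref"] + c["skipped_alt"]
        if n_inc < 1 or n_skip < 1:
            continue  # both isoforms must be represented
        p, minor, tie = splicing_ase_bound(
            c["included_ref"], c["included_alt"],
            c["skipped_ref"], c["skipped_alt"])
        out.append(SplicingEvent(
            gene_id=gene_id, junction_id=junction_id,
            included_ref=c["included_ref"], included_alt=c["included_alt"],
            skipped_ref=c["skipped_ref"], skipped_alt=c["skipped_alt"],
            p_bound=p, minor_isoform=minor, tie=tie,
        ))
    return out
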