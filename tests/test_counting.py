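"""Filtered allele counting and gene aggregation."""

import numpy as np
import pandas as pd
import pytest

from asepool import (
    FilterConfig,
    GeneModel,
    ReadObservation,
    SnpRecord,
    aggregate_to_gene,
    count_alleles,
)
from conftest import make_observations

NO_FILTERS = FilterConfig(min_mean_quality=0.0, exclude_snp_types=False,
                          require_unique=False, orientation_match=False)


class TestCountAlleles:
    def test_no_observations(self):
        res = count_alleles([], [SnpRecord("chr1", 5, "A", "G")])
        assert len(res.counts) == 0
        assert res.n_mismatch == 0

    def test_error_prone_snp_type_dropped(self):
        """A G/T site disappears entirely when type exclusion is on."""
        snp = SnpRecord("chr1", 50, "G", "T")
        obs = make_observations(snp, n_ref=3, n_alt=2)
        res = count_alleles(obs, [snp])
        assert len(res.counts) == 0
        res_off = count_alleles(obs, [snp], FilterConfig(exclude_snp_types=False))
        assert len(res_off.counts) == 1

    def test_manual_tally_with_mismatch(self):
        """10 reads: 6 ref, 3 alt, 1 neither -> counts (6, 3), mismatch 1."""
        snp = SnpRecord("chr1", 50, "A", "G")
        obs = make_observations(snp, n_ref=6, n_alt=3, n_other=1)
        res = count_alleles(obs, [snp])
        row = res.counts.iloc[0]
        assert (row.ref_count, row.alt_count) == (6, 3)
        assert res.n_mismatch == 1
        assert row.mean_quality == 30.0

    def test_low_mean_quality_site_dropped(self):
        snp = SnpRecord("chr1", 50, "A", "G")
        obs = make_observations(snp, n_ref=5, n_alt=5, qual=19)
        assert len(count_alleles(obs, [snp]).counts) == 0
        assert len(count_alleles(obs, [snp],
                                 FilterConfig(min_mean_quality=19)).counts) == 1

    def test_mean_quality_pools_both_strands(self):
        """Site mean quality is computed before the strand split."""
        snp = SnpRecord("chr1", 50, "A", "G")
        obs = (make_observations(snp, 4, 0, strand="+", qual=10, prefix="p")
               + make_observations(snp, 0, 4, strand="-", qual=40, prefix="m"))
        res = count_alleles(obs, [snp])  # site mean 25 >= 20: both strands kept
        assert set(res.counts.strand) == {"+", "-"}
        gone = count_alleles(obs, [snp], FilterConfig(min_mean_quality=26))
        assert len(gone.counts) == 0

    def test_non_unique_reads_dropped(self):
        snp = SnpRecord("chr1", 50, "A", "G")
        obs = (make_observations(snp, 3, 0, unique=True)
               + make_observations(snp, 0, 4, unique=False, prefix="x"))
        row = count_alleles(obs, [snp]).counts.iloc[0]
        assert (row.ref_count, row.alt_count) == (3, 0)

    def test_unknown_position_skipped_and_counted(self):
        snp = SnpRecord("chr1", 50, "A", "G")
        stray = ReadObservation("s", "chr1", 999, "+", "A", 30)
        res = count_alleles(make_observations(snp, 2, 1) + [stray], [snp])
        assert res.n_unknown_position == 1
        assert int(res.counts.ref_count.sum()) == 2

    def test_disabling_filters_reproduces_raw_tallies(self, rng, random_snps):
        """With every filter off, counts equal the raw per-site tallies."""
        obs = []
        expected = {}
        for snp in random_snps[:20]:
            n_ref, n_alt = int(rng.integers(0, 8)), int(rng.integers(0, 8))
            unique = bool(rng.integers(0, 2))
            qual = int(rng.integers(2, 41))
            obs += make_observations(snp, n_ref, n_alt, qual=qual,
                                     unique=unique, prefix=f"s{snp.pos}")
            if n_ref + n_alt:
                expected[(snp.chrom, snp.pos)] = (n_ref, n_alt)
        res = count_alleles(obs, random_snps, NO_FILTERS)
        got = {(r.chrom, r.pos): (r.ref_count, r.alt_count)
               for r in res.counts.itertuples()}
        assert got == expected


GENE_PLUS = GeneModel("gp", "chr1", "+", 0, 1000)


def _counts_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "ref_allele",
                                       "alt_allele", "ref_count", "alt_count",
                                       "mean_quality"])


class TestAggregateToGene:
    def test_two_snps_rejected_min_snps(self):
        frame = _counts_frame([
            ("chr1", 10, "+", "A", "G", 25, 5, 30.0),
            ("chr1", 20, "+", "A", "G", 8, 2, 30.0),
        ])
        (row,) = aggregate_to_gene(frame, [GENE_PLUS]).itertuples()
        assert row.status == "min_snps"
        assert row.n_snps_informative == 2

    def test_majority_vote_accepted(self):
        """Votes (ref, ref, alt) with 12 reads: accepted, 2 of 3 agree."""
        frame = _counts_frame([
            ("chr1", 10, "+", "A", "G", 4, 0, 30.0),
            ("chr1", 20, "+", "A", "G", 3, 1, 30.0),
            ("chr1", 30, "+", "A", "G", 1, 3, 30.0),
        ])
        (row,) = aggregate_to_gene(frame, [GENE_PLUS]).itertuples()
        assert row.status == "ok"
        assert row.n_snps_agreeing == 2
        assert (row.total_ref, row.total_alt) == (8, 4)

    def test_even_split_fails_majority(self):
        frame = _counts_frame([
            ("chr1", 10, "+", "A", "G", 4, 0, 30.0),
            ("chr1", 20, "+", "A", "G", 0, 4, 30.0),
            ("chr1", 30, "+", "A", "G", 2, 2, 30.0),  # tie vote abstains
            ("chr1", 40, "+", "A", "G", 2, 2, 30.0),
        ])
        (row,) = aggregate_to_gene(frame, [GENE_PLUS]).itertuples()
        assert row.status == "majority_disagreement"

    def test_opposite_strand_counts_excluded(self):
        frame = _counts_frame([
            ("chr1", 10, "+", "A", "G", 4, 1, 30.0),
            ("chr1", 10, "-", "A", "G", 50, 0, 30.0),
            ("chr1", 20, "+", "A", "G", 4, 0, 30.0),
            ("chr1", 30, "+", "A", "G", 4, 0, 30.0),
        ])
        (row,) = aggregate_to_gene(frame, [GENE_PLUS]).itertuples()
        assert row.total_ref + row.total_alt == 13

    def test_gene_without_snps_reports_reason(self):
        out = aggregate_to_gene(_counts_frame([]), [GENE_PLUS])
        assert out.iloc[0].status == "no_informative_snps"

    def test_reads_below_minimum_rejected(self):
        frame = _counts_frame([
            ("chr1", 10, "+", "A", "G", 2, 0, 30.0),
            ("chr1", 20, "+", "A", "G", 3, 1, 30.0),
            ("chr1", 30, "+", "A", "G", 2, 1, 30.0),
        ])
        (row,) = aggregate_to_gene(frame, [GENE_PLUS]).itertuples()
        assert row.status == "min_reads"

    def test_shared_snp_contributes_to_both_genes_and_is_flagged(self):
        g2 = GeneModel("g2", "chr1", "+", 5, 2000)
        frame = _counts_frame([
            ("chr1", 10, "+", "A", "G", 5, 0, 30.0),
            ("chr1", 20, "+", "A", "G", 5, 0, 30.0),
            ("chr1", 30, "+", "A", "G", 5, 0, 30.0),
        ])
        out = aggregate_to_gene(frame, [GENE_PLUS, g2])
        assert (out.total_ref == 15).all()
        assert out.shared_snps.all()

    def test_assignment_never_manufactures_reads(self, rng):
        """Sum of per-gene totals <= sum of matching-strand SNP counts."""
        genes = [GeneModel(f"g{i}", "chr1", "+", i * 500, i * 500 + 600)
                 for i in range(5)]  # deliberately overlapping
        rows = []
        for pos in rng.choice(np.arange(1, 3000), size=30, replace=False):
            rows.append(("chr1", int(pos), "+", "A", "G",
                         int(rng.integers(0, 10)), int(rng.integers(0, 10)), 30.0))
        frame = _counts_frame(rows)
        out = aggregate_to_gene(frame, genes)
        per_gene = (out.total_ref + out.total_alt).sum()
        raw = int(frame.ref_count.sum() + frame.alt_count.sum())
        # every SNP lands in at most 2 of these staggered genes
        assert per_gene <= 2 * raw
        single = aggregate_to_gene(frame, [GeneModel("g", "chr1", "+", 0, 3001)])
        assert int((single.total_ref + single.total_alt).sum()) == raw
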