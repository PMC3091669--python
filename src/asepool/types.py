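"""Shared data model for the pooled-ASE pipeline.

Coordinate conventions: positions stored on records that mirror VCF/GTF
(``SnpRecord.pos``) are 1-based; all interval arithmetic inside the package
uses 0-based half-open intervals (``GeneModel`` spans and exons, probe
intervals).  Conversion happens only at I/O boundaries.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

VALID_BASES = frozenset("ACGT")

#: Ordered (ref, alt) base pairs excluded from allele counting.  These SNP
#: classes showed disproportionate reference-mismatch error rates in
#: strand-specific short-read data and are dropped by default.
EXCLUDED_SNP_TYPES = frozenset({("C", "A"), ("A", "C"), ("G", "T")})


def is_excluded_snp_type(ref_allele: str, alt_allele: str) -> bool:
    """True when the ordered (ref, alt) pair is an error-prone SNP class."""
    return (ref_allele, alt_allele) in EXCLUDED_SNP_TYPES


@dataclass(frozen=True)
class SnpRecord:
    """A strain-distinguishing variant site.

    ``ref_allele`` is the reference-strain (B6) base; ``alt_allele`` the
    alternative strain (BTBR or CAST).  ``pos`` is 1-based, as in VCF.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            base = getattr(self, name)
            if base not in VALID_BASES:
                raise ValueError(f"{name} must be one of A/C/G/T, got {base!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt allele identical at {self.chrom}:{self.pos}")

    @property
    def excluded_type(self) -> bool:
        return is_excluded_snp_type(self.ref_allele, self.alt_allele)

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open interval covered by the SNP."""
        return (self.pos - 1, self.pos)


@dataclass(frozen=True)
class ReadObservation:
    """One aligned read's base call over one SNP.

    ``unique`` marks reads that aligned uniquely (or redundant reads anchored
    by a unique overlap).  ``junction_id``/``isoform`` are set only for reads
    spanning an alternative splice junction; ``isoform`` is "included" or
    "skipped".
    """

    read_id: str
    chrom: str
    pos: int  # 1-based SNP position
    strand: str
    observed_base: str
    base_quality: int
    unique: bool = True
    junction_id: str | None = None
    isoform: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.observed_base not in VALID_BASES | {"N"}:
            raise ValueError(f"observed base must be A/C/G/T/N, got {self.observed_base!r}")
        if self.base_quality < 0:
            raise ValueError("base quality must be non-negative")
        if (self.junction_id is None) != (self.isoform is None):
            raise ValueError("junction_id and isoform must be set together")
        if self.isoform is not None and self.isoform not in ("included", "skipped"):
            raise ValueError(f"isoform must be 'included' or 'skipped', got {self.isoform!r}")


@dataclass(frozen=True)
class AlleleCount:
    """Per-SNP, per-strand reference/alternate read tallies."""

    chrom: str
    pos: int
    strand: str
    ref_count: int
    alt_count: int
    mean_quality: float = math.nan

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: span plus exon structure, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end}) for {self.gene_id}")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon [{s}, {e}) outside span of {self.gene_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"exons of {self.gene_id} overlap or are unsorted")
            prev_end = e

    def contains(self, pos_1based: int) -> bool:
        """Whether a 1-based position falls inside the transcript span
        (introns included)."""
        return self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class GeneASE:
    """Gene-level aggregated allele counts with the binomial ASE statistic.

    ``lbp`` is the signed log10 binomial p: negative when bias is toward the
    B6/reference allele.
    """

    gene_id: str
    total_ref: int
    total_alt: int
    n_snps_informative: int
    n_snps_agreeing: int
    p0: float
    binomial_p: float
    lbp: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0):
            raise ValueError(f"p0 must be in (0, 1), got {self.p0}")
        if not (0.0 < self.binomial_p <= 1.0):
            raise ValueError(f"binomial_p must be in (0, 1], got {self.binomial_p}")


@dataclass(frozen=True)
class EqtlResult:
    """Single-marker regression summary for one gene at its own locus.

    ``additive_effect`` is the slope of the additive genotype coding; under a
    balanced design it equals half the homozygote mean difference, positive
    when BTBR homozygotes express higher.
    """

    gene_id: str
    lod: float
    additive_effect: float
    excluded_probe_snp: bool = False

    def __post_init__(self) -> None:
        if self.lod < 0:
            raise ValueError("LOD must be non-negative")
        if not math.isfinite(self.additive_effect):
            raise ValueError("additive effect must be finite")


@dataclass(frozen=True)
class PoolSpec:
    """Genotype composition of the pooled animals at one locus.

    Codes count BTBR alleles: BB (code 0) homozygous reference,
    Bb heterozygous, bb (code 2) homozygous alternative.
    """

    n_bb_ref: int
    n_het: int
    n_bb_alt: int

    def __post_init__(self) -> None:
        if min(self.n_bb_ref, self.n_het, self.n_bb_alt) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.pool_size == 0:
            raise ValueError("empty pool")

    @property
    def pool_size(self) -> int:
        return self.n_bb_ref + self.n_het + self.n_bb_alt

    @property
    def p0(self) -> float:
        """Expected reference-allele fraction among pooled transcripts."""
        return (2 * self.n_bb_ref + self.n_het) / (2 * self.pool_size)


@dataclass(frozen=True)
class FilterConfig:
    """Read/SNP filters applied before allele counting."""

    min_mean_quality: float = 20.0
    exclude_snp_types: bool = True
    require_unique: bool = True
    orientation_match: bool = True

    def __post_init__(self) -> None:
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")


@dataclass(frozen=True)
class PowerQuery:
    """Specification of an exact binomial power calculation.

    ``fold`` is the allelic fold difference; the alternative allele
    probability is fold / (fold + 1).
    """

    n: int
    fold: float
    alpha: float = 0.05
    tails: str = "one"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("coverage n must be >= 1")
        if self.fold < 1.0:
            raise ValueError("fold must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")

    @property
    def p1(self) -> float:
        return self.fold / (self.fold + 1.0)


@dataclass(frozen=True)
class AntisenseSite:
    """Per-SNP bidirectional transcription summary after normalization."""

    snp_id: str
    sense_ref: int
    sense_alt: int
    antisense_ref: int
    antisense_alt: int
    lbp_sense: float
    lbp_antisense: float
    site_class: str  # same_allele | antidirectional | unclassified


@dataclass(frozen=True)
class SplicingEvent:
    """Allele tables of the two isoforms at an alternative splice junction."""

    gene_id: str
    junction_id: str
    included_ref: int
    included_alt: int
    skipped_ref: int
    skipped_alt: int
    p_bound: float
    minor_isoform: str
    tie: bool = False


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Tabulate a homogeneous collection of dataclass records."""
    records = list(records)
    if not records:
        return pd.DataFrame()
    cls = type(records[0])
    if any(type(r) is not cls for r in records):
        raise TypeError("records must be a homogeneous collection")
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def frame_to_records(cls, frame: pd.DataFrame) -> list:
    """Inverse of :func:`records_to_frame` for a known dataclass."""
    names = [f.name for f in dataclasses.fields(cls)]
    out = []
    for row in frame.itertuples(index=False):
        kwargs = {n: getattr(row, n) for n in names if hasattr(row, n)}
        for key, val in list(kwargs.items()):
            if isinstance(val, float) and math.isnan(val) and key in ("junction_id", "isoform"):
                kwargs[key] = None
        out.append(cls(**kwargs))
    return out
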