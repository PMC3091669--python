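"""Readers and writers for the standard formats the pipeline consumes.

Formats
-------
SNP tables
    Sites-only VCF 4.x (read through :mod:`pysam`) or a 4-column TSV
    ``chrom  pos  ref_allele  alt_allele`` with header.  Positions 1-based.
Read observations
    SAM (read through pysam; one observation per read x overlapped SNP) or
    the flat TSV dialect defined here with columns
    ``read_id chrom pos strand base qual unique junction_id isoform``.
    The TSV dialect is the lingua franca of the test suite because raw
    alignment is out of scope.  In SAM input, uniqueness is taken from
    MAPQ > 0 on a non-secondary alignment, and junction/isoform labels are
    read from the optional ``ZJ:Z``/``ZI:Z`` tags when present (SAM has no
    standard encoding for isoform support).
Gene models
    BED12 (native 0-based half-open) or GTF (1-based, converted on read).
Stage outputs
    TSV with a header row; probabilities rendered with >= 6 significant
    digits.
"""

from __future__ import annotations

import dataclasses
import math
import os
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .types import (
    GeneModel,
    ReadObservation,
    SnpRecord,
    VALID_BASES,
)

OBSERVATION_COLUMNS = [
    "read_id", "chrom", "pos", "strand", "base", "qual", "unique",
    "junction_id", "isoform",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _infer_format(path: str, choices: dict[str, str]) -> str:
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext in choices:
        return choices[ext]
    raise ValueError(f"cannot infer format of {path!r}; pass format= explicitly")


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snp_table(path, format: str | None = None) -> list[SnpRecord]:
    """Read strain-distinguishing SNPs from VCF or TSV.

    Records are returned sorted by (chrom, pos); duplicate positions are a
    hard error because every per-SNP statistic downstream assumes unique
    sites.
    """
    fmt = format or _infer_format(path, {"vcf": "vcf", "tsv": "tsv", "txt": "tsv"})
    if fmt == "vcf":
        records = _read_snp_vcf(path)
    elif fmt == "tsv":
        records = _read_snp_tsv(path)
    else:
        raise ValueError(f"unknown SNP table format {fmt!r}")
    records.sort(key=lambda r: (r.chrom, r.pos))
    seen: set[tuple[str, int]] = set()
    for rec in records:
        key = (rec.chrom, rec.pos)
        if key in seen:
            raise ParseError(f"duplicate SNP position {rec.chrom}:{rec.pos}")
        seen.add(key)
    return records


def _read_snp_vcf(path) -> list[SnpRecord]:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for var in vcf:
            if var.alts is None or len(var.alts) != 1:
                raise ParseError(
                    f"SNP VCF must be biallelic: {var.chrom}:{var.pos}")
            records.append(SnpRecord(var.chrom, var.pos, var.ref.upper(),
                                     var.alts[0].upper()))
    return records


def _read_snp_tsv(path) -> list[SnpRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("chrom", "chr", "chromosome"):
                continue
            if len(fields) < 4:
                raise ParseError(f"line {lineno}: expected 4 columns, got {len(fields)}")
            chrom, pos, ref, alt = fields[:4]
            try:
                records.append(SnpRecord(chrom, int(pos), ref.upper(), alt.upper()))
            except ValueError as err:
                raise ParseError(f"line {lineno}: {err}") from err
    return records


def write_snp_table(records: Sequence[SnpRecord], path, format: str | None = None) -> None:
    fmt = format or _infer_format(path, {"vcf": "vcf", "tsv": "tsv", "txt": "tsv"})
    if fmt == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            contigs = sorted({r.chrom for r in records})
            for chrom in contigs:
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
                fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\t.\t.\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref_allele\talt_allele\n")
            for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
                fh.write(f"{r.chrom}\t{r.pos}\t{r.ref_allele}\t{r.alt_allele}\n")
    else:
        raise ValueError(f"unknown SNP table format {fmt!r}")


# ---------------------------------------------------------------------------
# Read observations
# ---------------------------------------------------------------------------

def read_observations(path, format: str | None = None,
                      snps: Sequence[SnpRecord] | None = None) -> list[ReadObservation]:
    """Read per-SNP read observations from the TSV dialect or SAM.

    For SAM input ``snps`` is required: each alignment is decomposed into one
    observation per overlapped SNP using the aligned pairs, taking the read
    base and base quality at the SNP's reference position.
    """
    fmt = format or _infer_format(path, {"tsv": "tsv", "txt": "tsv", "sam": "sam"})
    if fmt == "tsv":
        return _read_observations_tsv(path)
    if fmt == "sam":
        if snps is None:
            raise ValueError("reading observations from SAM requires the SNP table")
        return _read_observations_sam(path, snps)
    raise ValueError(f"unknown observation format {fmt!r}")


def _read_observations_tsv(path) -> list[ReadObservation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "read_id":
                continue
            if len(fields) != len(OBSERVATION_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(OBSERVATION_COLUMNS)} columns,"
                    f" got {len(fields)}")
            (read_id, chrom, pos, strand, base, qual, unique,
             junction_id, isoform) = fields
            if qual == "" or qual == ".":
                raise ParseError(f"line {lineno}: missing base quality")
            try:
                out.append(ReadObservation(
                    read_id=read_id, chrom=chrom, pos=int(pos), strand=strand,
                    observed_base=base.upper(), base_quality=int(qual),
                    unique=unique in ("1", "true", "True"),
                    junction_id=junction_id or None,
                    isoform=isoform or None,
                ))
            except ValueError as err:
                raise ParseError(f"line {lineno}: {err}") from err
    return out


def _read_observations_sam(path, snps: Sequence[SnpRecord]) -> list[ReadObservation]:
    by_chrom: dict[str, dict[int, SnpRecord]] = {}
    for snp in snps:
        by_chrom.setdefault(snp.chrom, {})[snp.pos - 1] = snp
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name not in by_chrom:
                continue
            sites = by_chrom[aln.reference_name]
            strand = "-" if aln.is_reverse else "+"
            unique = (not aln.is_secondary) and aln.mapping_quality > 0
            junction_id = aln.get_tag("ZJ") if aln.has_tag("ZJ") else None
            isoform = aln.get_tag("ZI") if aln.has_tag("ZI") else None
            quals = aln.query_qualities
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                snp = sites.get(rpos)
                if snp is None:
                    continue
                base = aln.query_sequence[qpos].upper()
                out.append(ReadObservation(
                    read_id=aln.query_name, chrom=snp.chrom, pos=snp.pos,
                    strand=strand, observed_base=base,
                    base_quality=int(quals[qpos]) if quals is not None else 0,
                    unique=unique, junction_id=junction_id, isoform=isoform,
                ))
    return out


def write_observations(observations: Sequence[ReadObservation], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(OBSERVATION_COLUMNS) + "\n")
        for o in observations:
            fh.write("\t".join([
                o.read_id, o.chrom, str(o.pos), o.strand, o.observed_base,
                str(o.base_quality), "1" if o.unique else "0",
                o.junction_id or "", o.isoform or "",
            ]) + "\n")


def observations_to_frame(observations: Sequence[ReadObservation]) -> pd.DataFrame:
    """Tabulate observations for vectorized counting."""
    return pd.DataFrame({
        "read_id": [o.read_id for o in observations],
        "chrom": [o.chrom for o in observations],
        "pos": [o.pos for o in observations],
        "strand": [o.strand for o in observations],
        "base": [o.observed_base for o in observations],
        "qual": [o.base_quality for o in observations],
        "unique": [o.unique for o in observations],
        "junction_id": [o.junction_id for o in observations],
        "isoform": [o.isoform for o in observations],
    })


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path, format: str | None = None) -> list[GeneModel]:
    fmt = format or _infer_format(path, {"bed": "bed", "gtf": "gtf"})
    if fmt == "bed":
        return _read_gene_models_bed12(path)
    if fmt == "gtf":
        return _read_gene_models_gtf(path)
    raise ValueError(f"unknown gene model format {fmt!r}")


def _read_gene_models_bed12(path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"line {lineno}: BED needs >= 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if len(fields) >= 12:
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                exons = tuple((start + off, start + off + sz)
                              for off, sz in zip(offsets, sizes))
            else:
                exons = ((start, end),)
            out.append(GeneModel(name, chrom, strand, start, end, exons))
    return out


def _read_gene_models_gtf(path) -> list[GeneModel]:
    import pyranges

    gr = pyranges.read_gtf(str(path)).df
    exons = gr[gr.Feature == "exon"]
    out = []
    id_col = "gene_id" if "gene_id" in exons.columns else "transcript_id"
    for gene_id, grp in exons.groupby(id_col, sort=True):
        grp = grp.sort_values("Start")
        ivals = tuple((int(s), int(e)) for s, e in zip(grp.Start, grp.End))
        out.append(GeneModel(
            gene_id=str(gene_id), chrom=str(grp.Chromosome.iloc[0]),
            strand=str(grp.Strand.iloc[0]),
            start=int(grp.Start.min()), end=int(grp.End.max()), exons=ivals,
        ))
    return out


def write_gene_models_bed12(models: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            exons = m.exons or ((m.start, m.end),)
            sizes = ",".join(str(e - s) for s, e in exons)
            offsets = ",".join(str(s - m.start) for s, e in exons)
            fh.write("\t".join([
                m.chrom, str(m.start), str(m.end), m.gene_id, "0", m.strand,
                str(m.start), str(m.end), "0", str(len(exons)), sizes, offsets,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Generic stage-output tables
# ---------------------------------------------------------------------------

def _render(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        if math.isnan(value):
            return "nan"
        return f"{value:.6g}"
    return str(value)


def write_results_table(records: Sequence, path, cls=None) -> None:
    """Write a homogeneous collection of dataclass records as headered TSV.

    ``cls`` names the record type explicitly; it is required to produce a
    header-only file from an empty collection.
    """
    records = list(records)
    with open(path, "w") as fh:
        if not records:
            if cls is None:
                raise ValueError("empty collection needs cls= to write a header")
            fh.write("\t".join(f.name for f in dataclasses.fields(cls)) + "\n")
            return
        cls = cls or type(records[0])
        if not dataclasses.is_dataclass(cls):
            raise TypeError("write_results_table expects dataclass records")
        if any(type(r) is not cls for r in records):
            raise TypeError("records must be a homogeneous collection")
        names = [f.name for f in dataclasses.fields(cls)]
        fh.write("\t".join(names) + "\n")
        for rec in records:
            fh.write("\t".join(_render(getattr(rec, n)) for n in names) + "\n")


def read_results_table(path, cls) -> list:
    """Read a table written by :func:`write_results_table` back as ``cls``."""
    frame = pd.read_csv(path, sep="\t")
    hints = {f.name: f.type for f in dataclasses.fields(cls)}
    out = []
    for _, row in frame.iterrows():
        kwargs = {}
        for name in hints:
            if name not in frame.columns:
                continue
            val = row[name]
            hint = str(hints[name])
            if "bool" in hint:
                val = bool(int(val)) if not isinstance(val, bool) else val
            elif hint.startswith("int"):
                val = int(val)
            elif hint.startswith("float"):
                val = float(val)
            elif isinstance(val, float) and math.isnan(val):
                val = None
            else:
                val = str(val)
            kwargs[name] = val
        out.append(cls(**kwargs))
    return out
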