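"""Synthetic data with the statistical structure of a pooled F2 ASE study.

Emulated design: an F2 intercross pool of 100 animals (per-locus genotypes
segregating 1:2:1), strand-specific reads over strain-distinguishing SNPs,
a configurable fraction of genes carrying true cis effects of a given
allelic fold change, replicate libraries sharing true allelic ratios,
bidirectional (antisense) sites, junction reads for included/skipped
isoforms, and an additive-genetic expression matrix over a larger profiled
cohort.  Every generator is deterministic under the configured seed.

The generative model is the exact inverse of the analysis model: at a SNP
in a gene with fold f favouring the reference allele, each read is
reference with probability p0*f / (p0*f + (1-p0)), where p0 is the pooled
reference-allele fraction at the gene's locus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    OBSERVATION_COLUMNS,
    write_gene_models_bed12,
    write_snp_table,
)
from .types import (
    EXCLUDED_SNP_TYPES,
    GeneModel,
    PoolSpec,
    SnpRecord,
)

__all__ = [
    "SimulationConfig", "simulate_f2_pool", "make_truth_table",
    "simulate_ase_reads", "simulate_ase_counts", "simulate_expression",
    "simulate_antisense_sites", "simulate_splicing_events",
    "write_simulation",
]

#: Ordered (ref, alt) pairs that survive the SNP-type exclusion filter.
_ALLOWED_PAIRS = [p for p in itertools.permutations("ACGT", 2)
                  if p not in EXCLUDED_SNP_TYPES]

_GENE_SPACING = 10_000
_GENE_LENGTH = 6_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pooled-ASE experiment.

    Defaults mirror the emulated design: a pool of 100 F2 animals, a
    profiled expression cohort of 500, per-SNP coverage 100, 3 SNPs per
    gene, 40% of genes with a 2.0-fold cis effect, and the 0.7% strand
    bleed-through ceiling of the library protocol.
    """

    seed: int
    n_animals: int = 100              # pooled for sequencing
    n_animals_expression: int = 500   # profiled on arrays
    n_genes: int = 200
    snps_per_gene: int = 3
    coverage: int = 100               # reads per SNP
    coverage_dispersion: str = "fixed"  # "fixed" | "poisson"
    cis_fraction: float = 0.4
    fold: float = 2.0                 # allelic fold at cis genes
    base_error_rate: float = 0.001
    base_quality: int = 35
    additive_effect: float = 0.5      # |slope| at cis genes (expression units)
    expression_noise_sd: float = 1.0
    direction_agreement: float = 1.0  # P(ASE and eQTL signs concordant)
    antisense_bleed_rate: float = 0.007
    n_antisense_sites: int = 200
    antisense_same_allele_fraction: float = 0.7
    antisense_coverage: int = 200
    antisense_allele_bias: float = 0.85
    n_splicing_events: int = 50
    splicing_coverage: int = 60
    splicing_psi_pair: tuple[float, float] = (0.9, 0.1)  # PSI of ref vs alt allele

    def __post_init__(self) -> None:
        for name in ("cis_fraction", "base_error_rate", "direction_agreement",
                     "antisense_bleed_rate", "antisense_same_allele_fraction",
                     "antisense_allele_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.fold < 1.0:
            raise ValueError("cis fold must be > 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _gene_layout(config: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping genes on chr1 with alternating strands."""
    models = []
    for g in range(config.n_genes):
        start = g * _GENE_SPACING + 1_000
        end = start + _GENE_LENGTH
        strand = "+" if g % 2 == 0 else "-"
        third = _GENE_LENGTH // 3
        exons = ((start, start + third), (end - third, end))
        models.append(GeneModel(f"gene{g:05d}", "chr1", strand, start, end, exons))
    return models


def simulate_f2_pool(config: SimulationConfig) -> tuple[pd.DataFrame, list[PoolSpec]]:
    """Genotypes of the pooled animals: one locus per gene, codes 0/1/2.

    Loci segregate independently as Binomial(2, 0.5) (Mendelian 1:2:1, no
    linkage).  Returns (animals x loci frame, per-locus PoolSpec).
    """
    rng = config.rng(stream=1)
    loci = [f"gene{g:05d}" for g in range(config.n_genes)]
    codes = rng.binomial(2, 0.5, size=(config.n_animals, config.n_genes))
    frame = pd.DataFrame(codes, columns=loci,
                         index=[f"animal{i:04d}" for i in range(config.n_animals)])
    specs = []
    for j in range(config.n_genes):
        col = codes[:, j]
        specs.append(PoolSpec(int((col == 0).sum()), int((col == 1).sum()),
                              int((col == 2).sum())))
    return frame, specs


def make_truth_table(config: SimulationConfig,
                     pool_specs: list[PoolSpec]) -> pd.DataFrame:
    """Per-gene ground truth: cis flag, fold, ASE direction, additive effect.

    ``direction`` is +1 when the reference (B6) allele is over-expressed.
    The additive effect is signed concordantly with the ASE direction
    (reference up => BTBR homozygotes lower => negative effect), flipped
    with probability 1 - direction_agreement.
    """
    rng = config.rng(stream=2)
    n = config.n_genes
    cis = rng.random(n) < config.cis_fraction
    direction = rng.choice([-1, 1], size=n)
    direction[~cis] = 0
    fold = np.where(cis, config.fold, 1.0)
    concordant = rng.random(n) < config.direction_agreement
    effect_sign = np.where(concordant, -direction, direction)
    additive = np.where(cis, effect_sign * config.additive_effect, 0.0)
    p0 = np.array([s.p0 for s in pool_specs])
    return pd.DataFrame({
        "gene_id": [f"gene{g:05d}" for g in range(n)],
        "cis": cis, "fold": fold, "direction": direction,
        "additive_effect": additive, "p0": p0,
    })


def _ref_probability(p0: np.ndarray, fold: np.ndarray,
                     direction: np.ndarray) -> np.ndarray:
    """Per-SNP probability a read shows the reference allele."""
    f_ref = np.where(direction > 0, fold, 1.0)
    f_alt = np.where(direction < 0, fold, 1.0)
    return p0 * f_ref / (p0 * f_ref + (1.0 - p0) * f_alt)


def simulate_ase_counts(config: SimulationConfig,
                        truth: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP allele counts drawn directly from the binomial model.

    Fast count-level twin of :func:`simulate_ase_reads` (no per-read
    records, no base errors).  Returns one row per SNP with gene_id, k
    (reference reads), n, p0 and the gene's truth columns.
    """
    rng = config.rng(stream=3)
    reps = config.snps_per_gene
    gene_idx = np.repeat(np.arange(config.n_genes), reps)
    p0 = truth["p0"].to_numpy()[gene_idx]
    fold = truth["fold"].to_numpy()[gene_idx]
    direction = truth["direction"].to_numpy()[gene_idx]
    ref_p = _ref_probability(p0, fold, direction)
    if config.coverage_dispersion == "poisson":
        n = np.maximum(rng.poisson(config.coverage, size=len(gene_idx)), 1)
    else:
        n = np.full(len(gene_idx), config.coverage)
    k = rng.binomial(n, ref_p)
    return pd.DataFrame({
        "gene_id": truth["gene_id"].to_numpy()[gene_idx],
        "snp_index": np.tile(np.arange(reps), config.n_genes),
        "k": k, "n": n, "p0": p0,
        "cis": truth["cis"].to_numpy()[gene_idx],
        "fold": fold, "direction": direction,
    })


def simulate_ase_reads(config: SimulationConfig, truth: pd.DataFrame):
    """Read-level observations over SNPs, plus the SNP table and gene models.

    Per SNP, coverage reads carry the reference allele with the model
    probability; each base is then corrupted to a uniformly chosen other
    base with ``base_error_rate``.  Reads take the gene's strand and are
    uniquely aligned.

    Returns ``(observations frame, snps, gene_models, snp_table)`` where the
    observations frame has the columns of the TSV dialect and ``snp_table``
    records the drawn (k, n) per SNP before base errors.
    """
    rng = config.rng(stream=4)
    models = _gene_layout(config)
    counts = simulate_ase_counts(config, truth)

    snp_records = []
    pair_idx = rng.integers(0, len(_ALLOWED_PAIRS), size=len(counts))
    positions = []
    step = max((_GENE_LENGTH - 400) // max(config.snps_per_gene, 1), 1)
    for row, pi in zip(counts.itertuples(index=False), pair_idx):
        g = int(row.gene_id.removeprefix("gene"))
        gm = models[g]
        pos = gm.start + 200 + step * int(row.snp_index) + 1  # 1-based
        ref, alt = _ALLOWED_PAIRS[pi]
        snp_records.append(SnpRecord("chr1", pos, ref, alt))
        positions.append(pos)
    counts = counts.assign(pos=positions,
                           ref_allele=[s.ref_allele for s in snp_records],
                           alt_allele=[s.alt_allele for s in snp_records])

    # expand to one row per read
    n_reads = counts["n"].to_numpy()
    snp_of_read = np.repeat(np.arange(len(counts)), n_reads)
    k = counts["k"].to_numpy()
    offsets = np.concatenate([[0], np.cumsum(n_reads)])[:-1]
    within = np.arange(n_reads.sum()) - offsets[snp_of_read]
    is_ref = within < k[snp_of_read]

    ref_b = counts["ref_allele"].to_numpy()[snp_of_read]
    alt_b = counts["alt_allele"].to_numpy()[snp_of_read]
    base = np.where(is_ref, ref_b, alt_b)

    if config.base_error_rate > 0:
        err = rng.random(len(base)) < config.base_error_rate
        if err.any():
            bases = np.array(list("ACGT"))
            repl = bases[rng.integers(0, 4, size=int(err.sum()))]
            cur = base[err]
            same = repl == cur
            while same.any():  # resample collisions so an error always changes the base
                repl[same] = bases[rng.integers(0, 4, size=int(same.sum()))]
                same = repl == cur
            base = base.copy()
            base[err] = repl

    strands = np.array(["+" if int(g.removeprefix("gene")) % 2 == 0 else "-"
                        for g in counts["gene_id"]])
    obs = pd.DataFrame({
        "read_id": [f"read{i:08d}" for i in range(len(base))],
        "chrom": "chr1",
        "pos": counts["pos"].to_numpy()[snp_of_read],
        "strand": strands[snp_of_read],
        "base": base,
        "qual": config.base_quality,
        "unique": True,
        "junction_id": None,
        "isoform": None,
    })[OBSERVATION_COLUMNS]
    return obs, snp_records, models, counts


def simulate_expression(config: SimulationConfig, truth: pd.DataFrame):
    """Additive-genetic expression matrix over the profiled cohort.

    expression_i = a * (genotype_i - 1) + Normal(0, sd).  Returns
    (expression genes x animals, genotypes animals x loci) for the
    expression cohort (drawn independently of the sequencing pool, as the
    profiled animals are a superset of the pooled ones in the emulated
    design).
    """
    rng = config.rng(stream=5)
    n_a = config.n_animals_expression
    codes = rng.binomial(2, 0.5, size=(n_a, config.n_genes))
    a = truth["additive_effect"].to_numpy()
    noise = rng.normal(0.0, config.expression_noise_sd,
                       size=(config.n_genes, n_a))
    expr = a[:, None] * (codes.T - 1.0) + noise
    animals = [f"xanimal{i:04d}" for i in range(n_a)]
    loci = truth["gene_id"].tolist()
    expression = pd.DataFrame(expr, index=loci, columns=animals)
    genotypes = pd.DataFrame(codes, index=animals, columns=loci)
    return expression, genotypes


def simulate_antisense_sites(config: SimulationConfig):
    """Strand-resolved allele counts at bidirectional SNPs, plus truth.

    Site modes: ``same_allele`` (both strands drawn from one allele-biased
    ratio), ``antidirectional`` (opposite allele bias per strand) and
    ``bleed_only`` (no true antisense transcription; the minor strand holds
    only bleed-through reads and should be removed by the bleed filter).
    One site in five is bleed-only; the rest split per
    ``antisense_same_allele_fraction``.
    """
    rng = config.rng(stream=6)
    n = config.n_antisense_sites
    modes = np.where(
        rng.random(n) < 0.2, "bleed_only",
        np.where(rng.random(n) < config.antisense_same_allele_fraction,
                 "same_allele", "antidirectional"))
    rows = []
    bias = config.antisense_allele_bias
    for i, mode in enumerate(modes):
        sid = f"as{i:04d}"
        n_sense = max(int(rng.poisson(config.antisense_coverage)), 1)
        ref_up = rng.random() < 0.5
        p_sense = bias if ref_up else 1.0 - bias
        if mode == "bleed_only":
            n_anti_true = 0
            p_anti = p_sense
        else:
            n_anti_true = max(int(rng.poisson(config.antisense_coverage // 2)), 1)
            p_anti = p_sense if mode == "same_allele" else 1.0 - p_sense
        # wrong-strand bleed-through from the sense strand
        n_bleed = rng.binomial(n_sense, config.antisense_bleed_rate)
        k_sense = rng.binomial(n_sense, p_sense)
        k_anti = rng.binomial(n_anti_true, p_anti) if n_anti_true else 0
        k_bleed = rng.binomial(n_bleed, p_sense) if n_bleed else 0
        rows.append({"snp_id": sid, "strand": "+",
                     "ref_count": int(k_sense),
                     "alt_count": int(n_sense - k_sense)})
        rows.append({"snp_id": sid, "strand": "-",
                     "ref_count": int(k_anti + k_bleed),
                     "alt_count": int(n_anti_true - k_anti + n_bleed - k_bleed)})
    counts = pd.DataFrame(rows)
    truth = pd.DataFrame({"snp_id": [f"as{i:04d}" for i in range(n)],
                          "mode": modes})
    return counts, truth


def simulate_splicing_events(config: SimulationConfig):
    """Junction-labeled observations for allele-specific splicing events.

    Each event sits in its own plus-strand gene with one SNP covered by
    junction reads of both isoforms.  Per allele, reads are split between
    included and skipped isoforms by the allele's PSI: shifted events use
    ``splicing_psi_pair`` (reference vs alternative allele); null events use
    equal PSI (mean of the pair) for both alleles.  Half the events are
    shifted.  Returns (observations frame, snps, gene_models, truth).
    """
    rng = config.rng(stream=7)
    n_ev = config.n_splicing_events
    shifted = rng.random(n_ev) < 0.5
    psi_ref_s, psi_alt_s = config.splicing_psi_pair
    psi_null = 0.5 * (psi_ref_s + psi_alt_s)

    models, snps, obs_rows, truth_rows = [], [], [], []
    read_no = 0
    for i in range(n_ev):
        start = i * _GENE_SPACING + 1_000
        gm = GeneModel(f"sgene{i:04d}", "chr2", "+", start, start + _GENE_LENGTH)
        models.append(gm)
        pos = start + _GENE_LENGTH // 2 + 1
        ref, alt = _ALLOWED_PAIRS[int(rng.integers(0, len(_ALLOWED_PAIRS)))]
        snps.append(SnpRecord("chr2", pos, ref, alt))
        psi_r, psi_a = (psi_ref_s, psi_alt_s) if shifted[i] else (psi_null, psi_null)
        n_total = max(int(rng.poisson(config.splicing_coverage)), 2)
        n_ref = rng.binomial(n_total, 0.5)
        for allele, n_allele, psi in (("ref", n_ref, psi_r),
                                      ("alt", n_total - n_ref, psi_a)):
            n_inc = rng.binomial(n_allele, psi) if n_allele else 0
            for iso, count in (("included", n_inc), ("skipped", n_allele - n_inc)):
                for _ in range(count):
                    obs_rows.append({
                        "read_id": f"jread{read_no:07d}", "chrom": "chr2",
                        "pos": pos, "strand": "+",
                        "base": ref if allele == "ref" else alt,
                        "qual": config.base_quality, "unique": True,
                        "junction_id": f"jx{i:04d}", "isoform": iso,
                    })
                    read_no += 1
        truth_rows.append({"gene_id": gm.gene_id, "junction_id": f"jx{i:04d}",
                           "shifted": bool(shifted[i]),
                           "psi_ref": psi_r, "psi_alt": psi_a})
    obs = pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS)
    return obs, snps, models, pd.DataFrame(truth_rows)


def write_simulation(config: SimulationConfig, outdir) -> dict[str, str]:
    """Generate a full dataset and write every stage input to ``outdir``.

    Emits snps.vcf, reads.tsv, genes.bed, geno.tsv (pool), expr.tsv and
    expr_geno.tsv (expression cohort), truth.tsv.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes, specs = simulate_f2_pool(config)
    truth = make_truth_table(config, specs)
    obs, snp_records, models, _ = simulate_ase_reads(config, truth)
    expression, expr_geno = simulate_expression(config, truth)

    paths = {
        "snps": str(outdir / "snps.vcf"),
        "reads": str(outdir / "reads.tsv"),
        "genes": str(outdir / "genes.bed"),
        "geno": str(outdir / "geno.tsv"),
        "expr": str(outdir / "expr.tsv"),
        "expr_geno": str(outdir / "expr_geno.tsv"),
        "truth": str(outdir / "truth.tsv"),
    }
    write_snp_table(snp_records, paths["snps"], format="vcf")
    obs_out = obs.copy()
    obs_out["unique"] = obs_out["unique"].astype(int)
    obs_out["junction_id"] = obs_out["junction_id"].fillna("")
    obs_out["isoform"] = obs_out["isoform"].fillna("")
    obs_out.to_csv(paths["reads"], sep="\t", index=False)
    write_gene_models_bed12(models, paths["genes"])
    genotypes.to_csv(paths["geno"], sep="\t")
    expression.to_csv(paths["expr"], sep="\t")
    expr_geno.to_csv(paths["expr_geno"], sep="\t")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
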