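# Methods

## Statistical model

Allele-specific expression is modelled per site as a sequence of
independent Bernoulli trials: each informative read over a heterozygous
strain-distinguishing SNP carries the reference-strain (B6) allele with
probability p₀ under the null of no allelic bias. In an F1 every animal is
heterozygous and p₀ = 0.5; in a pooled F2 sample the null fraction is the
pooled genotype frequency of the reference allele at the locus,
p₀ = (2·n_BB + n_Bb)/(2·N). Genotype-derived p₀ is clamped to
[0.01, 0.99] with a warning — a (near-)monomorphic pool carries no allelic
contrast and the binomial test is meaningless there.

The per-site statistic is the exact binomial tail
p = min(P(X ≤ k), P(X ≥ k)). Two conventions deserve emphasis:

* **The tail is the smaller single tail, not doubled.** This convention
  reproduces the published candidate-table p-values and the 82% power
  figure exactly; a conventional doubled two-sided p is available via a
  flag. The cost of the convention is that under the null
  Pr(p ≤ t) ≈ 2t for small t, because the tail direction is chosen from
  the data. Consequently calibration statements at nominal level α hold
  for the *directional* one-sided test (the convention the power
  calculation uses), and the test suite checks the min-tail statistic
  against its exact null guarantee Pr(p ≤ t) ≤ 2t.
* **LBP = ±(−log₁₀ p)**, base 10 so that thresholds compose with LOD
  scores (LBP > 2 ⇔ p < 0.01). The sign is negative when bias is toward
  the B6 allele and exactly 0 when k/n = p₀ (no defined direction; such
  genes are excluded from direction-agreement denominators).

## Filters before counting

Reads must be uniquely aligned (or anchored by unique overlaps); sites
whose mean base quality over contributing reads — both strands pooled,
since the filtered artifact is the site, not the strand — falls below
phred 20 are dropped; the ordered SNP classes C/A, A/C and G/T are dropped
as systematically error-prone in this library chemistry. Bases matching
neither allele are discarded and reported in a mismatch counter, giving a
visible handle on residual error. Gene aggregation sums counts over all
SNPs inside the transcript span (introns included — most intronic reads
are unspliced pre-mRNA) in the transcript's orientation, and requires at
least 3 informative SNPs, at least 10 summed count units, and strict
majority agreement among per-SNP direction votes. A vote is
sign(ref·(1−p₀) − alt·p₀); exact ties abstain. A read overlapping k SNPs
contributes k count units, and a SNP inside two overlapping same-strand
genes contributes to both (deterministic and symmetric; such genes are
flagged `shared_snps`).

## cis-eQTL stage

Each gene is regressed on the additive coding (−1, 0, +1) of its own
locus only; cis effects are expected to be additive, so no dominance term
is fitted and no genome-wide scan is run. LOD = (n/2)·log₁₀(RSS₀/RSS₁)
with RSS₁ floored at 10⁻¹² of RSS₀ to keep noise-free fixtures finite;
zero-variance expression returns (LOD 0, effect 0). The additive effect is
the slope — under a balanced design exactly half the homozygote mean
difference — positive when BTBR homozygotes express higher. Genes whose
array probes contain a SNP (half-open interval test) are excluded from
the comparison, since probe-SNP hybridization artifacts mimic cis-eQTL.

## Overlap expectation

For call sets of sizes n_array and n_seq among n_all testable genes, the
null same-direction overlap is n_array·n_seq/(2·n_all); the ½ is the
probability two independent signs agree. The any-direction expectation
(without the ½) is reported alongside, since published overlap counts can
be read either way. Enrichment is observed/expected per cell of a
threshold grid (|additive effect| × |LBP|), with direction agreement
computed among overlapping genes with a defined direction.

## Antisense classification

Sites with reads on both strands are screened against strand
bleed-through: with up to 0.7% of reads assigned to the wrong strand, a
site is kept only when its minor strand's count has
P(X ≥ minor | Binomial(total, 0.007)) < 10⁻⁴/n_tests (Bonferroni over the
bidirectional sites in the dataset). The filter direction — keep only
sites whose minor strand *exceeds* bleed-through — is the only reading
that removes artifacts; it is applied before per-strand mean-centering of
LBP (filter first, then normalize among survivors). Classification is by
the sign pair of the centered scores; the prevalence of same-allele over
antidirectional sites is tested with a one-sided exact sign test at ½.

## Splicing bound

An event requires junction reads of both isoforms covering a SNP, in the
transcript's orientation. The statistic is the one-sided binomial tail of
the allele split of the isoform with fewer total reads (a tie uses the
more balanced isoform and is flagged). It is a *bound* on the evidence
for allele-specific splicing, not a joint test: transcription-level ASE
shifts both isoforms together, so only the differential shift of the
minor isoform is scored. No multiple-testing correction is applied; the
output is a candidate list.

## Power

Exact binomial power: the critical value c is the smallest count with
P(X ≥ c | n, p₀) ≤ α (α/2 per side for the two-tailed variant), and
power = P(X ≥ c | n, p₁) with p₁ = fold/(fold+1) (scaled by p₀ for
unbalanced pools). `detectable_fold` inverts by bisection, valid because
power is non-decreasing in fold. At n = 100, α = 0.05 and fold = 1.70
this gives 0.8226. Note the exact convention gives 0.54 (not 0.50) at
α = 0.01, n = 100, fold = 1.70, and a detectable fold of 1.16 (not 1.18)
at n = 1000, α = 0.01, 50% power; the exact procedure behind those two
companion figures is not recoverable, so only the 82% figure is treated
as reproducible.

## Excess-ASE estimator

The fraction of SNPs "more allele-specific than expected" is estimated as
the largest gap between the observed CDF of per-SNP min-tail p-values and
the exact expected null CDF — the average over SNPs, each at its own
(n, p₀), of the null mass on achievable p-values — evaluated on the
achievable p-value grid. This is a concrete instantiation of an
observed-vs-expected distribution comparison; it is validated by
parameter recovery on synthetic data (recovering a simulated 40% biased
fraction within ±0.07 at fold 2, coverage 100), not against any real-data
fraction. The estimator is conservative at moderate folds: the max-gap of
a 40% mixture at fold 2.0/coverage 100 is analytically ≈ 0.35, and it
drops below the ±0.07 band at fold 1.7 — weak effects partially hide
under the null distribution.

## Replicate error model

Replicate agreement is quantified as |Δ log₂(allelic ratio)| per shared
SNP, with a Haldane–Anscombe pseudocount of 0.5 applied only when a cell
is zero (and never in test statistics). Each pair of replicates gets a
simulated twin drawn binomially at the same depths from the pooled ratio;
the observed and simulated error distributions are compared with the
Wilcoxon rank-sum test. Under a correct binomial error model the rank-sum
p is uniform, which the suite verifies by KS test over repeated draws.

## Synthetic-data generator

`SimulationConfig` defaults encode the emulated study: a pool of 100 F2
animals (independent Mendelian 1:2:1 loci — the analyses never exploit
inter-locus linkage, so none is simulated), an expression cohort of 500
animals, 3 SNPs per gene at coverage 100, 40% of genes with a 2.0-fold
cis effect applied multiplicatively to a randomly chosen allele,
base-call errors at 0.1%, additive expression effects of ±0.5 SD with
ASE/eQTL sign concordance 1.0, antisense sites at 0.7% bleed-through, and
junction reads at PSI 0.9 vs 0.1 for shifted splicing events. Test and
example problem sizes (200–10,000 genes depending on the statistic's
variance) were chosen so Monte-Carlo error is small relative to each
check's tolerance.

What the generator does *not* emulate: transcript-level read positioning
(reads are attached directly to SNPs), alignment bias toward the
reference genome, quality-score variation beyond a flat phred, linkage
disequilibrium, library-composition biases of pooling by unequal mass,
and overdispersion beyond binomial sampling. Passing recovery tests
therefore demonstrate correctness of the statistics under the stated
model, not robustness to those real-data artifacts; the mean-centering
step and the mismatch counter are the pipeline's only defences against
reference bias and base error respectively.

## Numerical and convention choices

* Coordinates: 1-based in VCF/GTF and the TSV dialects, 0-based half-open
  internally and in BED; conversion only at I/O boundaries.
* Duplicate SNP positions are a hard parse error — per-SNP statistics
  assume unique sites.
* Binomial tails come from scipy's regularized incomplete-beta
  implementation; the suite pins them to direct pmf summation up to
  n = 200.
* The confidence envelope d(n) grows the retention set symmetrically
  about n/2 in order of |2k − n| until ≥ 1−α mass is held; by
  construction the excluded null mass is ≤ α (0.66% at n = 100, α = 1%).
* Bisection tolerances: 10⁻⁶ on fold; RSS floor 10⁻¹²; p-values clipped
  into (0, 1].

## Known limitations

Beta-binomial overdispersion, FDR/q-value machinery, genome-wide eQTL
scans, read realignment and duplicate marking are out of scope. The
splicing bound conditions only on both isoforms being represented, not on
transcription-level ASE beyond that. The eQTL LOD is from a simplified
additive-only fit and is not claimed equivalent to full interval-mapping
pipelines.
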