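"""Validating sequencing ASE calls against array cis-eQTL.

Simulates the paired design — the same genes scored by pooled sequencing
(binomial ASE) and by single-marker regression on a 500-animal expression
cohort — and measures overlap enrichment and direction-of-bias agreement.
"""

import pandas as pd

from asepool import (
    SimulationConfig,
    enrichment_grid,
    gene_ase,
    make_truth_table,
    marker_regression,
    simulate_ase_counts,
    simulate_expression,
    simulate_f2_pool,
)

config = SimulationConfig(seed=7, n_genes=1000)
_, specs = simulate_f2_pool(config)
truth = make_truth_table(config, specs)

counts = simulate_ase_counts(config, truth)
gene_counts = counts.groupby("gene_id").agg(
    k=("k", "sum"), n=("n", "sum"), p0=("p0", "first")).reset_index()
ase = pd.DataFrame([
    {"gene_id": g.gene_id, "lbp": g.lbp}
    for g in (gene_ase(r.gene_id, int(r.k), int(r.n - r.k), float(r.p0))
              for r in gene_counts.itertuples(index=False))])

expression, genotypes = simulate_expression(config, truth)
eqtl = pd.DataFrame([
    {"gene_id": g, "lod": res.lod, "additive_effect": res.additive_effect}
    for g in truth.gene_id
    for res in [marker_regression(expression.loc[g].to_numpy(),
                                  genotypes[g].to_numpy())]])

grid = enrichment_grid(eqtl[eqtl.lod > 3], ase,
                       effect_thresholds=[0.0, 0.1, 0.2],
                       lbp_thresholds=[0.0, 1.0, 2.0],
                       n_all=config.n_genes)
cols = ["effect_threshold", "lbp_threshold", "n_overlap_same_direction",
        "ratio_same_direction", "direction_agreement"]
print(grid[cols].to_string(index=False))
# The observed/expected ratio climbs as both thresholds tighten, and the
# direction of allelic bias agrees for nearly all jointly called genes —
# the qualitative signature of two technologies measuring the same
# cis-acting variation.
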