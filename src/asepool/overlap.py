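"""Agreement between sequencing-based ASE calls and array-based cis-eQTL.

The two technologies measure the same underlying quantity — allelic
imbalance driven by heterozygous *cis*-acting variants — so genes called by
both, with the same direction of strain bias, validate each other.  The
null expectation for same-direction overlap of independent call sets is

    expected = (n_array / n_all) * (n_seq / n_all) * n_all * 1/2

the 1/2 arising because two independent directions agree half the time.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["expected_overlap", "enrichment_grid", "fisher_overlap"]


def expected_overlap(n_array: int, n_seq: int, n_all: int,
                     same_direction: bool = True) -> float:
    """Null expected count of genes called by both technologies.

    With ``same_direction=True`` (default) the expectation carries the 1/2
    factor for independent sign agreement; without it, the plain
    margin-product expectation for any-direction overlap.
    """
    if n_all <= 0:
        raise ValueError("n_all must be positive")
    if not (0 <= n_array <= n_all and 0 <= n_seq <= n_all):
        raise ValueError("margins must lie in [0, n_all]")
    expected = n_array * n_seq / n_all
    return expected / 2.0 if same_direction else expected


def enrichment_grid(eqtl_results: pd.DataFrame,
                    ase_results: pd.DataFrame,
                    effect_thresholds: Sequence[float],
                    lbp_thresholds: Sequence[float],
                    n_all: int) -> pd.DataFrame:
    """Observed/expected overlap across a grid of confidence thresholds.

    ``eqtl_results`` needs columns gene_id, additive_effect (signed);
    ``ase_results`` needs gene_id, lbp (signed; negative = B6-biased).
    Directions agree when sign(lbp) == sign(additive_effect): positive lbp
    and positive additive effect both mean the BTBR allele is the
    over-expressed one.  Genes with lbp exactly 0 carry no direction and are
    excluded from direction-agreement denominators.

    Returns a long-format frame with one row per (effect_threshold,
    lbp_threshold) cell: margins, same/any-direction overlap, expected
    counts, observed/expected ratios and direction agreement.
    """
    if len(effect_thresholds) == 0 or len(lbp_thresholds) == 0:
        raise ValueError("threshold axes must be non-empty")
    merged = eqtl_results[["gene_id", "additive_effect"]].merge(
        ase_results[["gene_id", "lbp"]], on="gene_id", how="outer")
    eff = merged["additive_effect"].to_numpy(float)
    lbp = merged["lbp"].to_numpy(float)

    rows = []
    for eff_thr in effect_thresholds:
        in_array = np.abs(eff) > eff_thr
        in_array &= ~np.isnan(eff)
        for lbp_thr in lbp_thresholds:
            in_seq = np.abs(lbp) > lbp_thr
            in_seq &= ~np.isnan(lbp)
            both = in_array & in_seq
            directed = both & (lbp != 0.0)
            same = directed & (np.sign(lbp) == np.sign(eff))
            n_array = int(in_array.sum())
            n_seq = int(in_seq.sum())
            n_overlap = int(both.sum())
            n_same = int(same.sum())
            n_directed = int(directed.sum())
            exp_same = expected_overlap(n_array, n_seq, n_all, True)
            exp_any = expected_overlap(n_array, n_seq, n_all, False)
            rows.append({
                "effect_threshold": eff_thr, "lbp_threshold": lbp_thr,
                "n_array": n_array, "n_seq": n_seq,
                "n_overlap": n_overlap,
                "n_overlap_same_direction": n_same,
                "expected_same_direction": exp_same,
                "expected_any_direction": exp_any,
                "ratio_same_direction": n_same / exp_same if exp_same > 0 else np.nan,
                "ratio_any_direction": n_overlap / exp_any if exp_any > 0 else np.nan,
                "direction_agreement": n_same / n_directed if n_directed > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def fisher_overlap(n_both: int, n_array_only: int, n_seq_only: int,
                   n_neither: int) -> float:
    """One-sided hypergeometric enrichment p of the 2x2 overlap table."""
    table = [[n_both, n_array_only], [n_seq_only, n_neither]]
    if min(n_both, n_array_only, n_seq_only, n_neither) < 0:
        raise ValueError("cell counts must be non-negative")
    _, p = sps.fisher_exact(table, alternative="greater")
    return float(p)
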