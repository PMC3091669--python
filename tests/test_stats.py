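"""Binomial ASE statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, kstest

from asepool import (
    PowerQuery,
    binomial_tail_p,
    ci_envelope,
    concordance,
    detectable_fold,
    excess_ase_fraction,
    gene_ase,
    lbp,
    power,
    replicate_error_analysis,
)


def brute_force_tail(k, n, p0):
    """Direct pmf summation oracle for the min single tail."""
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    return min(math.fsum(pmf[: k + 1]), math.fsum(pmf[k:]))


class TestBinomialTail:
    @pytest.mark.parametrize("k,n,expected", [
        (5, 5, 0.03125),            # 5:0 split
        (2, 6, 0.34375),            # 2:4 split
        (9, 30, 22964087 / 2**30),  # exact dyadic value
        (3, 6, 0.65625),            # both tails overlap the center
    ])
    def test_fair_coin_tails(self, k, n, expected):
        assert binomial_tail_p(k, n, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_never_doubled_but_doubling_available(self):
        assert binomial_tail_p(5, 5, 0.5, doubled=True) == pytest.approx(0.0625)
        assert binomial_tail_p(3, 6, 0.5, doubled=True) == 1.0

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ValueError, match="informative"):
            binomial_tail_p(0, 0, 0.5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(1, 200), kf=st.floats(0, 1),
           p0=st.sampled_from([0.3, 0.5, 0.55]))
    def test_matches_brute_force_summation(self, n, kf, p0):
        k = int(round(kf * n))
        assert binomial_tail_p(k, n, p0) == pytest.approx(
            brute_force_tail(k, n, p0), rel=1e-9, abs=1e-300)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n=st.integers(1, 150), kf=st.floats(0, 1))
    def test_symmetric_at_half(self, n, kf):
        k = int(round(kf * n))
        assert binomial_tail_p(k, n, 0.5) == pytest.approx(
            binomial_tail_p(n - k, n, 0.5), rel=1e-12)

    def test_monotone_away_from_null_mean(self):
        """The tail p falls as k moves away from n*p0 on either side."""
        for n, p0 in [(50, 0.5), (80, 0.3)]:
            k = np.arange(n + 1)
            p = binomial_tail_p(k, n, p0)
            center = n * p0
            below = p[k <= math.floor(center)]
            above = p[k >= math.ceil(center)]
            assert np.all(np.diff(below) >= -1e-12)
            assert np.all(np.diff(above) <= 1e-12)


class TestLbp:
    def test_reference_bias_is_negative(self):
        assert lbp(5, 5, 0.5) == pytest.approx(math.log10(0.03125))  # -1.50515
        assert lbp(5, 5, 0.5) == pytest.approx(-1.50515, abs=1e-5)

    def test_mirror_symmetry(self):
        assert lbp(0, 5, 0.5) == pytest.approx(1.50515, abs=1e-5)
        assert lbp(0, 5, 0.5) == -lbp(5, 5, 0.5)

    def test_exact_null_ratio_has_no_direction(self):
        assert lbp(3, 6, 0.5) == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n=st.integers(1, 120), kf=st.floats(0, 1))
    def test_antisymmetric_under_allele_swap(self, n, kf):
        k = int(round(kf * n))
        assert lbp(k, n, 0.5) == pytest.approx(-lbp(n - k, n, 0.5), abs=1e-12)


class TestGeneAse:
    def test_balanced_counts_are_null(self):
        g = gene_ase("g", 30, 30, 0.5)
        assert g.lbp == 0.0
        assert g.binomial_p > 0.3

    def test_totals_use_exact_summation(self):
        g = gene_ase("g", 60, 40, 0.5)
        assert g.binomial_p == pytest.approx(brute_force_tail(60, 100, 0.5),
                                             rel=1e-9)
        assert g.lbp < 0  # reference-biased

    def test_pool_aware_null_neutralizes_matching_ratio(self):
        g = gene_ase("g", 60, 40, 0.6)
        assert g.lbp == 0.0

    def test_monomorphic_pool_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            gene_ase("g", 5, 5, 1.0)


class TestCiEnvelope:
    def test_brute_force_enumeration_n10(self):
        """At n=10, only 0:10 and 10:0 splits fall outside 99%."""
        assert ci_envelope(10, alpha=0.01) == 8

    def test_nothing_excluded_at_n1(self):
        assert ci_envelope(1, alpha=0.01) == 1

    def test_vectorized_over_n(self):
        d = ci_envelope(np.array([1, 10, 100]), alpha=0.01)
        assert list(d) == [1, 8, ci_envelope(100, 0.01)]

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            ci_envelope(10, alpha=1.5)

    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_monte_carlo_coverage(self, rng, alpha):
        """Null SNPs at n=100 fall outside the envelope at most alpha often."""
        n = 100
        d = ci_envelope(n, alpha=alpha)
        k = rng.binomial(n, 0.5, size=100_000)
        outside = np.abs(2 * k - n) > d
        assert outside.mean() <= alpha + 3 * math.sqrt(alpha / 100_000)


class TestReplicateError:
    def _counts(self, rng, n_snps=300, depth=80):
        n = rng.poisson(depth, n_snps) + 2
        k = rng.binomial(n, 0.5)
        return pd.DataFrame({"snp_id": [f"s{i}" for i in range(n_snps)],
                             "ref_count": k, "alt_count": n - k})

    def test_identical_replicates_have_zero_error(self, rng):
        c = self._counts(rng)
        frame, _ = replicate_error_analysis(c, c.copy(), seed=1)
        assert (frame.observed_error == 0).all()

    def test_error_decreases_with_depth(self, rng):
        """Deep SNPs (n >= 100) show smaller replicate error than shallow."""
        rows = []
        for i, n in enumerate([15] * 200 + [150] * 200):
            k1, k2 = rng.binomial(n, 0.5, 2)
            rows.append((f"s{i}", k1, n - k1, k2, n - k2))
        c1 = pd.DataFrame([(r[0], r[1], r[2]) for r in rows],
                          columns=["snp_id", "ref_count", "alt_count"])
        c2 = pd.DataFrame([(r[0], r[3], r[4]) for r in rows],
                          columns=["snp_id", "ref_count", "alt_count"])
        frame, _ = replicate_error_analysis(c1, c2, seed=2)
        deep = frame[frame.mean_reads >= 100].observed_error.median()
        shallow = frame[frame.mean_reads < 30].observed_error.median()
        assert deep < shallow

    def test_ranksum_p_uniform_under_null(self, rng):
        """Binomial replicates are indistinguishable from their simulated
        twins: the rank-sum p is uniform over repeated draws."""
        ps = []
        for rep in range(60):
            n = rng.poisson(60, 150) + 2
            k1 = rng.binomial(n, 0.5)
            k2 = rng.binomial(n, 0.5)
            c1 = pd.DataFrame({"snp_id": range(150), "ref_count": k1,
                               "alt_count": n - k1})
            c2 = pd.DataFrame({"snp_id": range(150), "ref_count": k2,
                               "alt_count": n - k2})
            _, p = replicate_error_analysis(c1, c2, seed=1000 + rep)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_shared_snps(self):
        c = pd.DataFrame({"snp_id": ["a"], "ref_count": [3], "alt_count": [4]})
        with pytest.raises(ValueError):
            replicate_error_analysis(c, c, seed=0)


class TestConcordance:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        r2, n, p = concordance(x, x)
        assert r2 == pytest.approx(1.0)
        assert n == 10

    def test_four_point_closed_form(self):
        """Direct formula: r^2 = cov^2 / (varx * vary) = 0.25 / 13.75."""
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 0.0])
        r2, n, _ = concordance(x, y)
        assert r2 == pytest.approx(0.25 / 13.75, rel=1e-12)

    def test_independent_values_have_tiny_r2(self, rng):
        r2s = [concordance(rng.normal(size=1000), rng.normal(size=1000))[0]
               for _ in range(9)]
        assert np.median(r2s) <= 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestExcessAse:
    def test_empty_input(self):
        with pytest.raises(ValueError):
            excess_ase_fraction(pd.DataFrame(columns=["k", "n", "p0"]))

    def test_maximally_null_counts_have_zero_excess(self):
        """Every SNP at the most probable split: nothing exceeds the null."""
        table = pd.DataFrame({"k": [50] * 40, "n": [100] * 40, "p0": 0.5})
        excess, _ = excess_ase_fraction(table)
        assert excess == pytest.approx(0.0, abs=1e-12)

    def test_null_simulation_recovers_zero(self):
        """Fully-null data: excess stays near 0 (median over seeds)."""
        vals = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            n = np.full(2000, 100)
            k = rng.binomial(n, 0.5)
            table = pd.DataFrame({"k": k, "n": n, "p0": 0.5})
            vals.append(excess_ase_fraction(table)[0])
        assert np.median(vals) <= 0.02

    def test_mixed_coverage_and_p0(self, rng):
        """Estimator runs on heterogeneous (n, p0) without error and stays
        bounded in [0, 1]."""
        n = rng.poisson(60, 500) + 10
        p0 = rng.uniform(0.4, 0.6, 500)
        k = rng.binomial(n, p0)
        excess, t = excess_ase_fraction(pd.DataFrame({"k": k, "n": n, "p0": p0}))
        assert 0.0 <= excess <= 1.0
        assert 0.0 < t <= 1.0


class TestPower:
    def test_reported_coverage100_case(self):
        """1.70-fold at 100x, alpha 0.05 one-tailed: 82% power."""
        pw = power(PowerQuery(n=100, fold=1.70, alpha=0.05, tails="one"))
        assert round(pw, 2) == 0.82

    def test_null_fold_never_beats_alpha(self):
        for n in (10, 100, 400):
            assert power(PowerQuery(n=n, fold=1.0, alpha=0.05)) <= 0.05

    def test_brute_force_enumeration_alpha001(self):
        """Exact enumeration oracle at alpha=0.01, one tail."""
        n, p1 = 100, 1.70 / 2.70
        c = next(c for c in range(n + 1)
                 if sum(math.comb(n, i) * 0.5**n for i in range(c, n + 1)) <= 0.01)
        expected = math.fsum(math.comb(n, i) * p1**i * (1 - p1) ** (n - i)
                             for i in range(c, n + 1))
        assert power(PowerQuery(n=100, fold=1.70, alpha=0.01)) == pytest.approx(
            expected, rel=1e-9)

    def test_monotone_in_n_and_fold(self):
        pws_n = [power(PowerQuery(n=n, fold=1.5, alpha=0.05))
                 for n in (50, 100, 200, 400)]
        assert pws_n == sorted(pws_n)
        pws_f = [power(PowerQuery(n=100, fold=f, alpha=0.05))
                 for f in (1.2, 1.5, 2.0, 3.0)]
        assert pws_f == sorted(pws_f)

    def test_two_tailed_less_powerful_than_one(self):
        one = power(PowerQuery(n=100, fold=1.7, alpha=0.05, tails="one"))
        two = power(PowerQuery(n=100, fold=1.7, alpha=0.05, tails="two"))
        assert two < one

    def test_unattainable_alpha_gives_zero(self):
        assert power(PowerQuery(n=3, fold=2.0, alpha=1e-6)) == 0.0

    def test_detectable_fold_inverts_power(self):
        f = detectable_fold(100, alpha=0.05, target_power=0.82)
        assert power(PowerQuery(n=100, fold=f, alpha=0.05)) >= 0.82
        assert power(PowerQuery(n=100, fold=f - 0.01, alpha=0.05)) < 0.82
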