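"""Allele frequencies, heterozygosities, F_IS, Weir-Cockerham theta, Jost D."""

import math

import numpy as np
import pytest

from clonescape.genotype_io import LocusGenotype, SampleRecord, SampleTable
from clonescape.popgen import (
    allele_frequencies,
    diversity_summary,
    jost_d,
    jost_dest,
    multilocus_fis,
    nei_unbiased_he,
    pairwise_differentiation,
    wc_fst,
    wc_theta,
)

from conftest import make_panel


def table_from_genotypes(genos, site="A", n_loci=None, panel=None, prefix="s"):
    """genos: list of per-individual locus tuples [(a,b), (a,b), ...]."""
    n_loci = n_loci or len(genos[0])
    panel = panel or make_panel(n_loci)
    records = [
        SampleRecord(
            sample_id=f"{prefix}{i:03d}",
            site=site,
            genotype=tuple(LocusGenotype(a, b) for a, b in g),
        )
        for i, g in enumerate(genos)
    ]
    return SampleTable(panel, records)


def hw_population(p, n, site="A", prefix="s"):
    """One biallelic locus in exact Hardy-Weinberg proportions (alleles 1, 2)."""
    n_aa = round(n * p * p)
    n_ab = round(n * 2 * p * (1 - p))
    n_bb = n - n_aa - n_ab
    genos = [[(1, 1)]] * n_aa + [[(1, 2)]] * n_ab + [[(2, 2)]] * n_bb
    return table_from_genotypes(genos, site=site, prefix=prefix)


class TestAlleleFrequencies:
    def test_simple_counting(self):
        t = table_from_genotypes([[(1, 1)], [(1, 2)]])
        f = allele_frequencies(t)
        assert f.freqs["L1"] == {1: 0.75, 2: 0.25}

    def test_genet_level_deduplicates_clones(self):
        t = table_from_genotypes([[(1, 2)]] * 10)
        f = allele_frequencies(t, level="genet")
        assert f.n_individuals == 1
        assert f.freqs["L1"] == {1: 0.5, 2: 0.5}

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        genos = [
            [tuple(sorted(rng.integers(1, 6, 2).tolist())) for _ in range(4)]
            for _ in range(30)
        ]
        f = allele_frequencies(table_from_genotypes(genos))
        for locus in f.freqs:
            assert sum(f.freqs[locus].values()) == pytest.approx(1.0)


class TestHeterozygosityAndFis:
    def test_unbiased_he_small_sample_closed_form(self):
        # AA, AB: p = 0.75, n = 2 -> (4/3) * (1 - 0.5625 - 0.0625) = 0.5
        t = table_from_genotypes([[(1, 1)], [(1, 2)]])
        assert nei_unbiased_he(t)["L1"] == pytest.approx(0.5)

    def test_all_heterozygotes_give_fis_minus_one(self):
        t = table_from_genotypes([[(1, 2)]] * 20)
        assert multilocus_fis(t) == pytest.approx(-1.0)

    def test_exact_hw_proportions_give_fis_near_zero(self):
        t = hw_population(0.6, 100)
        s = diversity_summary(t, n_perm=199, seed=11)
        assert abs(s.f_is) < 0.05
        assert s.hwe_p > 0.05
        assert s.h_o == pytest.approx(0.48)

    def test_monomorphic_panel_is_degenerate(self):
        t = table_from_genotypes([[(1, 1)]] * 10)
        s = diversity_summary(t, n_perm=0, seed=0)
        assert s.n_a == 1.0
        assert s.h_e == 0.0
        assert math.isnan(s.f_is)

    def test_heterozygote_excess_detected_as_hwe_departure(self):
        t = table_from_genotypes([[(1, 2)]] * 40 + [[(1, 1)]] * 2 + [[(2, 2)]] * 2)
        s = diversity_summary(t, n_perm=199, seed=5)
        assert s.f_is < -0.5
        assert s.hwe_p < 0.05

    def test_private_alleles_scored_against_comparison_set(self):
        a = table_from_genotypes([[(1, 2)], [(1, 3)]], site="A")
        b = table_from_genotypes([[(1, 1)], [(1, 2)]], site="B")
        s = diversity_summary(a, comparison_set=[b], n_perm=0, seed=0)
        assert s.n_ap == 1.0  # allele 3 private to A


class TestWcTheta:
    def test_identical_frequencies_give_theta_near_zero(self):
        a = hw_population(0.5, 200, site="A", prefix="a")
        b = hw_population(0.5, 200, site="B", prefix="b")
        res = wc_fst(a, b, n_perm=99, seed=3)
        assert abs(res.fst) < 0.01
        assert res.fst_p > 0.05

    def test_fixed_different_alleles_give_theta_one(self):
        a = table_from_genotypes([[(1, 1)]] * 20, site="A", prefix="a")
        b = table_from_genotypes([[(2, 2)]] * 20, site="B", prefix="b")
        res = wc_fst(a, b, n_perm=0, seed=0)
        assert res.fst == pytest.approx(1.0)

    def test_symmetric_in_the_pair_and_under_relabelling(self):
        rng = np.random.default_rng(7)
        genos_a = [
            [tuple(sorted(rng.integers(1, 4, 2).tolist())) for _ in range(3)]
            for _ in range(15)
        ]
        genos_b = [
            [tuple(sorted(rng.integers(2, 5, 2).tolist())) for _ in range(3)]
            for _ in range(12)
        ]
        a = table_from_genotypes(genos_a, site="A", prefix="a")
        b = table_from_genotypes(genos_b, site="B", prefix="b")
        assert wc_theta([a, b]) == pytest.approx(wc_theta([b, a]), abs=1e-12)
        relabel = {1: 10, 2: 20, 3: 30, 4: 40}
        genos_a2 = [[(relabel[x], relabel[y]) for x, y in g] for g in genos_a]
        genos_b2 = [[(relabel[x], relabel[y]) for x, y in g] for g in genos_b]
        a2 = table_from_genotypes(genos_a2, site="A", prefix="a")
        b2 = table_from_genotypes(genos_b2, site="B", prefix="b")
        assert wc_theta([a2, b2]) == pytest.approx(wc_theta([a, b]), abs=1e-12)


class TestJostD:
    def test_identical_populations_give_d_near_zero(self):
        a = hw_population(0.5, 100, site="A", prefix="a")
        b = hw_population(0.5, 100, site="B", prefix="b")
        assert abs(jost_d([a, b])) < 0.02

    def test_disjoint_high_diversity_gives_d_near_one(self):
        genos_a = [[(2 * i + 1, 2 * i + 2)] for i in range(10)] * 2
        genos_b = [[(2 * i + 101, 2 * i + 102)] for i in range(10)] * 2
        a = table_from_genotypes(genos_a, site="A", prefix="a")
        b = table_from_genotypes(genos_b, site="B", prefix="b")
        assert jost_d([a, b]) > 0.9

    def test_ramet_dest_exceeds_genet_dest_under_clonal_dominance(self):
        # one population dominated by a single clone: deduplicating genets
        # removes most of the apparent differentiation
        rng = np.random.default_rng(21)
        clone = [[(1, 2), (3, 4), (1, 3)]]
        rare = [
            [tuple(sorted(rng.integers(1, 5, 2).tolist())) for _ in range(3)]
            for _ in range(6)
        ]
        a = table_from_genotypes(clone * 40 + rare, site="A", prefix="a")
        genos_b = [
            [tuple(sorted(rng.integers(1, 5, 2).tolist())) for _ in range(3)]
            for _ in range(40)
        ]
        b = table_from_genotypes(genos_b, site="B", prefix="b")
        ramet = jost_dest(a, b, n_perm=0, seed=0, level="ramet").dest
        genet = jost_dest(a, b, n_perm=0, seed=0, level="genet").dest
        assert ramet >= genet


class TestPermutationNull:
    def test_split_panmictic_population_gives_uniformish_p(self):
        # one pool split at random should rarely look differentiated
        rng = np.random.default_rng(3)
        pvals = []
        for rep in range(25):
            genos = [
                [tuple(sorted(rng.integers(1, 5, 2).tolist())) for _ in range(3)]
                for _ in range(40)
            ]
            a = table_from_genotypes(genos[:20], site="A", prefix=f"a{rep}_")
            b = table_from_genotypes(genos[20:], site="B", prefix=f"b{rep}_")
            pvals.append(wc_fst(a, b, n_perm=99, seed=rep).fst_p)
        assert np.mean(np.array(pvals) <= 0.05) < 0.25
        assert np.mean(pvals) > 0.3
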