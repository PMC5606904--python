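"""Clone identification, genotype probabilities and MLL collapse."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonescape.clones import (
    call_clones,
    collapse_mll,
    identify_mlgs,
    mll_threshold,
    p_gen,
    p_sex,
    probability_of_identity,
)
from clonescape.genotype_io import LocusGenotype, SampleRecord, SampleTable
from clonescape.networks import MLGDistanceMatrix
from clonescape.popgen import AlleleFrequencies

from conftest import clone_table, make_panel, make_random_table


def freqs(per_locus: dict[str, dict[int, float]], n: int = 50) -> AlleleFrequencies:
    return AlleleFrequencies(
        freqs=per_locus, n_copies={k: 2 * n for k in per_locus}, n_individuals=n
    )


class TestIdentifyMlgs:
    def test_groups_identical_genotypes(self):
        table = clone_table([3, 2])
        mlgs = identify_mlgs(table)
        assert [m.n_copies for m in mlgs] == [3, 2]
        assert [m.mlg_id for m in mlgs] == ["MLG01", "MLG02"]

    def test_within_locus_allele_order_is_canonical(self, small_table):
        mlgs = identify_mlgs(small_table)
        by_size = {m.n_copies for m in mlgs}
        assert by_size == {2, 1}  # a1 and a2 differ only in allele order
        assert len(mlgs) == 3

    def test_invariant_to_record_order(self):
        table = clone_table([4, 3, 1, 1], seed=9)
        rev = SampleTable(table.panel, list(reversed(table.records)))
        a = identify_mlgs(table)
        b = identify_mlgs(rev)
        assert [(m.mlg_id, m.genotype) for m in a] == [
            (m.mlg_id, m.genotype) for m in b
        ]

    def test_missing_data_is_a_precondition_error(self):
        table = make_random_table(seed=1, n=10, missing_rate=0.5)
        with pytest.raises(ValueError, match="missing"):
            identify_mlgs(table)


class TestProbabilityOfIdentity:
    def test_biallelic_even_locus(self):
        f = freqs({"L1": {1: 0.5, 2: 0.5}})
        assert probability_of_identity(f).p_id == pytest.approx(0.375)

    def test_product_over_two_loci(self):
        f = freqs({"L1": {1: 0.5, 2: 0.5}, "L2": {1: 0.5, 2: 0.5}})
        assert probability_of_identity(f).p_id == pytest.approx(0.140625)

    def test_monomorphic_locus_is_certain_identity(self):
        f = freqs({"L1": {1: 1.0}})
        assert probability_of_identity(f).per_locus["L1"] == pytest.approx(1.0)

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError, match="empty"):
            probability_of_identity(freqs({}))

    def test_adding_a_locus_never_increases_p_id(self):
        one = freqs({"L1": {1: 0.6, 2: 0.4}})
        two = freqs({"L1": {1: 0.6, 2: 0.4}, "L2": {1: 0.9, 2: 0.1}})
        assert probability_of_identity(two).p_id <= probability_of_identity(one).p_id

    def test_unbiased_estimator_close_to_naive_at_large_n(self):
        f = freqs({"L1": {1: 0.5, 2: 0.3, 3: 0.2}}, n=5000)
        naive = probability_of_identity(f, "naive").p_id
        unbiased = probability_of_identity(f, "unbiased").p_id
        assert unbiased == pytest.approx(naive, rel=0.01)


class TestPGen:
    def test_heterozygote_hwe(self):
        f = freqs({"L1": {1: 0.5, 2: 0.5}})
        g = (LocusGenotype(1, 2),)
        assert p_gen(g, f) == pytest.approx(0.5)

    def test_two_locus_product(self):
        f = freqs({"L1": {1: 0.5, 2: 0.5}, "L2": {1: 0.2, 2: 0.8}})
        g = (LocusGenotype(1, 2), LocusGenotype(1, 1))
        assert p_gen(g, f) == pytest.approx(0.5 * 0.04)

    def test_extreme_heterozygote_excess_clamps_to_one(self):
        f = freqs({"L1": {1: 0.5, 2: 0.5}})
        g = (LocusGenotype(1, 2),)
        assert p_gen(g, f, fis={"L1": -1.0}) == pytest.approx(1.0)

    def test_absent_allele_errors(self):
        f = freqs({"L1": {1: 1.0}})
        with pytest.raises(ValueError, match="absent"):
            p_gen((LocusGenotype(1, 2),), f)


class TestPSex:
    def test_degenerate_bounds(self):
        assert p_sex(0.0, 1, 10) == 0.0
        assert p_sex(1.0, 10, 10) == 1.0

    def test_matches_binomial_tail(self):
        assert p_sex(0.1, 2, 10) == pytest.approx(0.2639, abs=5e-5)

    def test_n_greater_than_big_n_errors(self):
        with pytest.raises(ValueError):
            p_sex(0.5, 11, 10)

    @given(
        pgen=st.floats(0.01, 0.99),
        N=st.integers(1, 40),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_single_occurrence_closed_form(self, pgen, N):
        assert p_sex(pgen, 1, N) == pytest.approx(1 - (1 - pgen) ** N, rel=1e-9)

    def test_monotone_in_pgen_N_and_n(self):
        grid = np.linspace(0.05, 0.95, 10)
        vals = [p_sex(p, 3, 20) for p in grid]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        vals_N = [p_sex(0.3, 3, N) for N in range(3, 30)]
        assert all(a <= b + 1e-12 for a, b in zip(vals_N, vals_N[1:]))
        vals_n = [p_sex(0.3, n, 30) for n in range(1, 30)]
        assert all(a >= b - 1e-12 for a, b in zip(vals_n, vals_n[1:]))


class TestCallClones:
    def test_all_distinct_yields_no_calls(self):
        table = clone_table([1, 1, 1, 1], seed=4)
        assert call_clones(table) == []

    def test_rare_repeat_at_common_genotype_is_flagged(self):
        # the double-heterozygote is the likeliest two-locus genotype under
        # random mating, so two copies among 10 are easily two sexual events
        genos = [
            (100, 101, 100, 101),
            (100, 101, 100, 101),
            (100, 100, 100, 101),
            (101, 101, 100, 100),
            (100, 100, 101, 101),
            (101, 101, 100, 101),
            (100, 101, 100, 100),
            (100, 101, 101, 101),
            (100, 100, 100, 100),
            (101, 101, 101, 101),
        ]
        panel = make_panel(2)
        records = [
            SampleRecord(
                sample_id=f"s{i}",
                site="A",
                genotype=(LocusGenotype(a, b), LocusGenotype(c, d)),
            )
            for i, (a, b, c, d) in enumerate(genos)
        ]
        calls = call_clones(SampleTable(panel, records))
        assert len(calls) == 1
        assert calls[0].p_sex > 0.05
        assert calls[0].distinct_events_flag

    def test_dominant_clone_has_tiny_p_sex(self):
        # 40 copies of one genotype among 44: not plausible without clonality
        table = clone_table([40, 1, 1, 1, 1], n_loci=9, seed=8)
        calls = call_clones(table)
        big = max(calls, key=lambda c: c.n_copies)
        assert big.p_sex < 1e-10
        assert not big.distinct_events_flag


def matrix_from(ids, pairs):
    n = len(ids)
    v = np.zeros((n, n))
    index = {k: i for i, k in enumerate(ids)}
    for (a, b), d in pairs.items():
        v[index[a], index[b]] = v[index[b], index[a]] = d
    return MLGDistanceMatrix(list(ids), v)


class TestMllThreshold:
    def test_gap_above_zero_gives_one_step(self):
        dist = matrix_from("ABC", {("A", "B"): 2, ("A", "C"): 3, ("B", "C"): 5})
        assert mll_threshold(dist) == 1

    def test_unit_distances_merge_below_first_gap(self):
        dist = matrix_from(
            "ABCD",
            {
                ("A", "B"): 1,
                ("C", "D"): 1,
                ("A", "C"): 4,
                ("A", "D"): 5,
                ("B", "C"): 5,
                ("B", "D"): 6,
            },
        )
        assert mll_threshold(dist) == 1

    def test_single_mlg_gives_zero(self):
        assert mll_threshold(MLGDistanceMatrix(["A"], np.zeros((1, 1)))) == 0

    def test_non_integer_distances_rejected(self):
        dist = matrix_from("AB", {("A", "B"): 1.5})
        with pytest.raises(ValueError, match="integer"):
            mll_threshold(dist)


class _FakeMLG:
    def __init__(self, mlg_id):
        self.mlg_id = mlg_id


class TestCollapseMll:
    def test_threshold_zero_keeps_every_mlg(self):
        dist = matrix_from("ABC", {("A", "B"): 1, ("A", "C"): 2, ("B", "C"): 2})
        part = collapse_mll([_FakeMLG(i) for i in "ABC"], dist, 0)
        assert part.n_lineages == 3

    def test_single_linkage_chain_merges_transitively(self):
        dist = matrix_from("ABC", {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 2})
        part = collapse_mll([_FakeMLG(i) for i in "ABC"], dist, 1)
        assert part.n_lineages == 1

    def test_threshold_at_max_distance_gives_one_lineage(self):
        dist = matrix_from("ABCD", {(a, b): 3 for a in "ABCD" for b in "ABCD" if a < b})
        part = collapse_mll([_FakeMLG(i) for i in "ABCD"], dist, 3)
        assert part.n_lineages == 1

    def test_merged_pairs_and_spectators(self):
        dist = matrix_from(
            "ABCD",
            {
                ("A", "B"): 1,
                ("C", "D"): 1,
                ("A", "C"): 4,
                ("A", "D"): 5,
                ("B", "C"): 5,
                ("B", "D"): 6,
            },
        )
        part = collapse_mll([_FakeMLG(i) for i in "ABCD"], dist, 1)
        assert part.n_lineages == 2
        assert part.assignment["A"] == part.assignment["B"]
        assert part.assignment["C"] == part.assignment["D"]
        assert part.assignment["A"] != part.assignment["C"]
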