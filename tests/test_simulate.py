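"""Synthetic partially clonal populations and the nested sampling design."""

import warnings

import numpy as np
import pytest

from clonescape.clones import identify_mlgs
from clonescape.diversity import clonal_richness, clone_sizes
from clonescape.genotype_io import (
    LocusDef,
    LocusGenotype,
    SampleRecord,
    SampleTable,
    drop_incomplete,
)
from clonescape.simulate import (
    GrowthModelParams,
    SamplingDesign,
    SimulationParams,
    inject_missing,
    nested_circular_sampling,
    simulate_clonal_population,
    von_bertalanffy_length,
)


class TestGrowthModel:
    def test_four_month_recruit_length(self):
        assert round(von_bertalanffy_length(4 / 12), 1) == 7.9

    def test_zero_length_at_t0(self):
        g = GrowthModelParams()
        assert von_bertalanffy_length(g.t0, g) == pytest.approx(0.0)

    def test_asymptote(self):
        g = GrowthModelParams()
        assert von_bertalanffy_length(500.0, g) == pytest.approx(34.224, abs=1e-6)

    def test_monotone_increasing(self):
        t = np.linspace(0, 20, 50)
        lengths = [von_bertalanffy_length(x) for x in t]
        assert all(a < b for a, b in zip(lengths, lengths[1:]))


def high_diversity_params(**kw):
    defaults = dict(
        alleles_per_locus=(6, 9),
        initial_population=200,
        n_seasons=4,
        missing_rate=0.0,
        somatic_mutation_rate=0.0,
        mortality_rate=0.05,
        carrying_capacity=400,
        seed=0,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestClonalPopulationSimulation:
    def test_ground_truth_genets_recovered_without_mutation(self):
        params = high_diversity_params(sexual_recruitment_rate=5.0, seed=10)
        table = simulate_clonal_population(params)
        mlgs = identify_mlgs(table)
        partition = {frozenset(m.member_ids) for m in mlgs}
        genets = {}
        for r in table.records:
            genets.setdefault(r.genet_id, set()).add(r.sample_id)
        assert partition == {frozenset(v) for v in genets.values()}

    def test_no_fission_no_mutation_mlg_count_equals_genets(self):
        params = high_diversity_params(
            fission_rate=0.0, sexual_recruitment_rate=0.0, seed=3
        )
        table = simulate_clonal_population(params)
        genets = {r.genet_id for r in table.records}
        assert len(identify_mlgs(table)) == len(genets)

    def test_pure_fission_keeps_richness_near_zero(self):
        params = SimulationParams(
            founder_count=3,
            alleles_per_locus=(6, 9),
            sexual_recruitment_rate=0.0,
            fission_rate=0.8,
            mortality_rate=0.0,
            n_seasons=8,
            somatic_mutation_rate=1e-3,
            missing_rate=0.0,
            seed=4,
        )
        table = simulate_clonal_population(params)
        sizes = clone_sizes(table)
        # G is at most the founders plus rare mutation-induced variants
        n_mutants = len(sizes) - 3
        assert n_mutants <= 5
        r = clonal_richness(len(table), len(sizes))
        assert r < 0.2

    def test_total_mortality_warns_of_extinction(self):
        params = SimulationParams(
            mortality_rate=1.0, n_seasons=2, missing_rate=0.0, seed=0
        )
        with pytest.warns(UserWarning, match="extinct"):
            table = simulate_clonal_population(params)
        assert len(table) == 0

    def test_richness_decreases_with_fission_rate(self):
        means = []
        for rate in (0.0, 0.3, 0.6):
            rs = []
            for rep in range(6):
                params = SimulationParams(
                    founder_count=25,
                    alleles_per_locus=(6, 9),
                    fission_rate=rate,
                    sexual_recruitment_rate=2.0,
                    mortality_rate=0.05,
                    n_seasons=8,
                    missing_rate=0.0,
                    somatic_mutation_rate=0.0,
                    seed=100 * rep + int(10 * rate),
                )
                table = simulate_clonal_population(params)
                rs.append(clonal_richness(len(table), len(identify_mlgs(table))))
            means.append(float(np.mean(rs)))
        assert means[0] > means[1] > means[2]


def uniform_population(n=3000, radius=45.0, seed=0):
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    panel = [LocusDef("L1")]
    records = [
        SampleRecord(
            sample_id=f"p{i:04d}",
            site="A",
            x=float(r[i] * np.cos(theta[i])),
            y=float(r[i] * np.sin(theta[i])),
            genotype=(LocusGenotype(100, 100),),
        )
        for i in range(n)
    ]
    return SampleTable(panel, records)


class TestNestedCircularSampling:
    def test_dense_population_yields_full_station(self):
        pop = uniform_population()
        sample = nested_circular_sampling(pop, seed=1)
        assert len(sample) == 64
        d = np.array([np.hypot(r.x, r.y) for r in sample.records])
        design = SamplingDesign()
        bounds = [(0, 5), (5, 10), (10, 20), (20, 40)]
        for lo, hi in bounds:
            assert ((d >= lo) & (d < hi)).sum() == design.per_strip

    def test_samples_lie_within_outer_radius(self):
        pop = uniform_population(seed=3)
        sample = nested_circular_sampling(pop, centre=(5.0, -3.0), seed=3)
        d = np.array([np.hypot(r.x, r.y) for r in sample.records])
        assert (d < 40.0).all()

    def test_no_individual_sampled_twice(self):
        pop = uniform_population(seed=5)
        sample = nested_circular_sampling(pop, seed=5)
        ids = [r.sample_id for r in sample.records]
        assert len(ids) == len(set(ids))

    def test_sparse_annulus_warns_and_shortens(self):
        pop = uniform_population(n=30, radius=4.0, seed=7)  # nothing beyond 5 m
        with pytest.warns(UserWarning, match="annulus"):
            sample = nested_circular_sampling(pop, seed=7)
        assert len(sample) < 64


class TestInjectMissing:
    def test_rate_zero_is_identity(self):
        pop = uniform_population(n=20)
        assert inject_missing(pop, 0.0, seed=0) is pop

    def test_rate_one_blanks_everything(self):
        pop = uniform_population(n=20)
        out = inject_missing(pop, 1.0, seed=0)
        assert all(g.is_missing for r in out.records for g in r.genotype)

    def test_matched_rate_reproduces_completeness_fraction(self):
        # per-locus rate r on a 1472 x 9 table: complete fraction (1-r)^9
        panel = [LocusDef(f"L{j}") for j in range(1, 10)]
        records = [
            SampleRecord(
                sample_id=f"s{i:04d}",
                site="A",
                genotype=tuple(LocusGenotype(100, 102) for _ in range(9)),
            )
            for i in range(1472)
        ]
        table = SampleTable(panel, records)
        rate = 0.0012
        out = inject_missing(table, rate, seed=13)
        kept, _ = drop_incomplete(out)
        expected = (1 - rate) ** 9
        se = np.sqrt(expected * (1 - expected) / 1472)
        assert abs(len(kept) / 1472 - expected) < 3 * se
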