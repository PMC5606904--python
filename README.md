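# clonescape

Clonal-structure analysis of codominant multilocus genotypes.

Many benthic marine invertebrates — fissiparous sea cucumbers and sea stars,
corals, seagrasses — reproduce both sexually (broadcast-spawned larvae) and
asexually (transverse fission or fragmentation, each piece regenerating a
complete individual). How much each mode contributes shapes a population's
genetic diversity, its connectivity and its management: clonal propagation
fixes a few genotypes locally, sexual dispersal links sites. `clonescape`
quantifies that balance from microsatellite genotype tables, for population
geneticists and for managers of exploited partially clonal species.

## What it computes

Given a table of diploid multilocus genotypes (MLGs) with sampling metadata:

- **Clone discrimination.** Identical MLGs define putative clones. The panel's
  probability of identity `P_ID = prod_l [ sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2 ]`
  gauges marker resolution; for each repeated MLG the package computes
  `P_gen` (genotype probability under random mating, optionally F_IS-adjusted)
  and `P_sex = P(X >= n), X ~ Binomial(N, P_gen)` — the probability that its
  n copies arose from independent sexual events. MLGs a few mutation steps
  apart can be collapsed into multilocus lineages (MLLs) at a threshold read
  off the first gap of the pairwise distance distribution.
- **Clonal diversity.** Clonal richness `R = (G-1)/(N-1)`, Pielou's evenness
  `J' = H'/ln G` and the Pareto exponent `beta` of the inverse cumulative
  clone-size distribution, per population.
- **Spatial structure.** Aggregation of clonemates `A_c` and edge effect
  `E_e` of unique genotypes within a sampling plot, with seeded permutation
  tests.
- **Genotype networks.** Stepwise-mutation (Rozenfeld) distances between
  MLGs, the percolation threshold `Dpe` at which the network fragments, and
  the mean clustering coefficient `<CC>`.
- **Differentiation.** Weir–Cockerham `F_ST` (theta) and Jost's `D_est`
  between populations, with permutation tests, at ramet level (all
  individuals) or genet level (one representative per MLG).
- **Sexual-only null.** For each population, the clonal richness expected if
  it were regenerated by sexual reproduction alone (alleles resampled from
  the observed gamete pool), with a Monte-Carlo p-value for the observed
  deficit — the formal test that low richness reflects fission, not weak
  markers.
- **Synthetic data.** A spatially explicit simulator of partially clonal
  populations (seasonal fission and sexual recruitment, somatic mutation,
  von Bertalanffy growth, nested circular-plot sampling) with ground-truth
  genet labels, used as the package's test bed.

## Worked example

Simulate a clonal population, identify its clones and test richness against
the sexual-only null:

```python
from clonescape import (SimulationParams, simulate_clonal_population,
                        drop_incomplete, identify_mlgs, call_clones,
                        clone_summary, null_richness_test)

params = SimulationParams(initial_population=300, carrying_capacity=300,
                          n_seasons=6, seed=42)
pop = simulate_clonal_population(params)
complete, removed = drop_incomplete(pop)
mlgs = identify_mlgs(complete)
summary = clone_summary(complete, spatial=False)
null = null_richness_test(complete, n_rep=999, seed=0)
```

prints (via the obvious f-strings):

```
286 individuals simulated, 1 with missing data removed
32 distinct MLGs; largest clone: MLG01 with 129 ramets
N=285 G=32 R=0.109 J'=0.57 beta=0.65
MLG01: n=129 P_gen=9.50e-06 P_sex(FIS)=0.00e+00 multi-event=False
MLG02: n=44 P_gen=1.06e-08 P_sex(FIS)=2.92e-272 multi-event=False
R_obs=0.109 R_sim=1.000 [1.000, 1.000] p=0.0010
```

Read: 285 complete genotypes collapse to 32 MLGs (richness 0.109 — strongly
clonal); the dominant clone's 129 copies cannot be independent sexual events
(P_sex ~ 0); and a purely sexual population with these allele frequencies
would have shown essentially all-distinct genotypes (R_sim = 1.0), so the
observed deficit is significant (p = 0.001).

The same analyses run from the shell on any annotated CSV or GenePop table:

```bash
clonescape run --in table.csv --outdir results/ --n-perm 1000 --seed 42
```

writing `clones.tsv`, `summary.tsv` (one row per population), `spatial.tsv`,
`fst_dest.tsv`, `nullsim.tsv`, `net.graphml` + `net_summary.tsv` and a
`run.log` recording the seeds behind every numeric cell.

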