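# Methods

This note records the statistical conventions, simulation assumptions and
open design choices behind `clonescape`, at the level of detail a user needs
to interpret its outputs or audit a disagreement with another package.

## Data model

The unit of analysis is a *population*: all individuals sampled at the same
place (station, or site when sampling was haphazard and the station field is
empty) on the same date (season within sampling period). Allele values are
stored as raw fragment sizes in base pairs; each locus carries a
`motif_length` (bp per repeat unit) used only when distances are expressed in
mutation steps. When motif lengths are unknown the default of 1 treats allele
values as already being in repeat units. Individuals with any missing locus
are excluded from clonal analyses (`drop_incomplete`); the popgen summaries
tolerate missing single-locus genotypes by locus-wise deletion.

## Clone discrimination

A clone is the set of individuals sharing a multilocus genotype (MLG), with
alleles canonically ordered within each locus. Marker adequacy is summarized
by the probability of identity; the naive estimator
`sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2` per locus (product over loci) is the
default, with the small-sample unbiased estimator available — the two differ
negligibly at the sample sizes this package targets.

For an MLG observed n times among N individuals, `P_sex` is the upper
binomial tail `P(X >= n)` with `X ~ Binomial(N, P_gen)`, computed through the
regularized incomplete beta function (no term-by-term cancellation). The
literature also contains conditional "(n-1 further occurrences)" variants;
the convention used here is recorded in the output metadata so results are
comparable across tools. `P_gen` uses population allele frequencies at ramet
level (clones included) — the frequencies the gamete pool actually sees in a
clonal population — with a genet-level option. The F_IS-adjusted variant
multiplies per-locus terms `p^2 + F p (1-p)` (homozygotes) or `2 p q (1-F)`
(heterozygotes), clamped to [0, 1], with per-locus F estimated as
`1 - H_O/H_E` in the population holding the plurality of the MLG's members.
Repeated MLGs with `P_sex(F_IS) > alpha` (default 0.05) are flagged as
possibly representing distinct reproductive events.

### Multilocus lineages

Distinct MLGs separated by very small stepwise distances are plausibly
somatic mutants or scoring errors of one lineage. The collapse threshold is
read off the unit-binned pairwise distance distribution: if one-step
distances exist, the threshold is the top of the contiguous run of occupied
unit bins starting at 1 (the first gap above that run separates
mutation-scale from recombination-scale differences); otherwise it sits in
the empty gap just below the smallest observed distance (`d_min - 1`), so
that nothing is merged. Collapse is single linkage: any two MLGs at distance
at most the threshold share a lineage, transitively.

## Distances and networks

The distance between two diploid genotypes is, per locus, the minimum over
the two possible allele pairings of the summed absolute differences in repeat
units, summed over loci. A single-step somatic mutation therefore moves a
genotype by exactly 1, which is what makes the unit-binned threshold logic
above meaningful. This is a metric (verified by randomized triple tests).

The genotype network takes MLGs as nodes. Scanning the unique distance values
as thresholds, the percolation threshold `Dpe` is the smallest threshold at
which the network remains one connected component; the components just below
`Dpe` are reported as the first clusters (the coarsest signal of restricted
gene flow). Network software in this area also offers a
susceptibility-peak definition; the susceptibility curve (mean non-giant
component size per threshold) is emitted so users can apply it, but the
connectivity break is the reported `Dpe`. `<CC>` is the mean unweighted local
clustering coefficient of the network thresholded at `Dpe` (degree < 2
contributes 0). Edges change only at observed distance values, so no
intermediate thresholds need scanning; ties are handled by scanning unique
values.

## Diversity indices

Clonal richness `R = (G-1)/(N-1)` (0 when N = 1). Pielou's `J' = H'/ln G` is
undefined (NA) for monoclonal samples rather than 0, since `ln G = 0`. The
Pareto exponent is minus the OLS slope of `ln N(>=X)` on `ln X` over the
distinct clone sizes X (natural logs, counts not fractions — the slope is
identical — ties collapsed to one regression point, no binning); a single
distinct size gives NA.

`H_O` is the observed heterozygote fraction, `H_E` Nei's unbiased expected
heterozygosity `(2N/(2N-1)) (1 - sum p^2)`, both averaged over loci with
between-locus standard errors. Multilocus F_IS is the Weir–Cockerham
within-population f — a ratio of variance components summed over alleles and
loci, not a plain mean of per-locus `1 - H_O/H_E` — and its Hardy–Weinberg
test permutes alleles among individuals within each locus, two-sided on |f|.
`N_ap` counts alleles absent from every other population supplied as the
comparison set, averaged over loci.

## Differentiation

`F_ST` is Weir–Cockerham theta via the a/b/c variance components summed over
alleles and loci (tested against an independently coded ANOVA-mean-squares
oracle to 1e-10). `D_est` is Jost's D per locus with Nei–Chesser unbiased
`H_S`/`H_T` (harmonic-mean sample size), `r/(r-1)` correction with r = 2,
averaged arithmetically over loci; loci with `H_S = 1` are skipped with a
warning. Permutation p-values reassign individuals between the two
populations. Ramet level is the default; genet level (one representative per
MLG per population) is a flag, and the pipeline reports both for pooled
high-density site pairs. Negative estimates are reported as computed, with a
floor-at-zero display column for table-style output. Pairwise matrices carry
raw permutation p-values; a Benjamini–Hochberg column can be added downstream
but is deliberately not the default.

## Spatial indices

`A_c = (P_sg - P_sp)/(1 - P_sp)`, where `P_sg` is the fraction of individuals
whose nearest neighbour (ties broken by sample-id order; coincident points
allowed) is a clonemate and `P_sp = sum n_i (n_i - 1) / (N (N - 1))`.
`E_e = (d_u - d_all)/d_all` compares mean distance-to-plot-centre of
single-copy MLGs against all individuals; the centre defaults to the station
origin, and whether an alternative (e.g. mean pairwise distance among unique
MLGs) was intended by other software is noted in the result metadata rather
than guessed. Both are tested one-sided by label permutation (A_c: clone
labels over fixed coordinates; E_e: which individuals count as unique).

Because `A_c` takes few distinct values at realistic N, permuted statistics
frequently tie the observed one, and the plain `(#{perm >= obs} + 1)/(B + 1)`
p-value is visibly conservative (its null distribution piles mass near 1).
The p-value therefore breaks ties randomly — a uniform draw over the tie
block from the same seeded generator — which is exactly uniform under label
exchangeability, never 0, always includes the observed statistic, and reduces
to the plain formula when no permutation ties. Results are reproducible
bit-for-bit at fixed seed and permutation count.

## Sexual-only richness null

Each observed population of size N is regenerated 10^3 times (configurable)
by drawing, for every individual and locus, two alleles from the population's
observed ramet-level allele frequencies — panmixia with selfing allowed,
unlinked loci, constant population size, one generation, no fission and no
mutation. The test reports the mean and empirical 2.5/97.5 percentiles of the
simulated richness and `p = (#{R_sim <= R_obs} + 1)/(B + 1)`: "as weak as
observed" is read as <= so that p stays in (0, 1]. Iterating further
generations would only drift the frequencies without changing the one-
generation genotype distribution the test needs.

## Synthetic populations and the simulated survey

The generator emulates a dense aggregation of a fissiparous holothurian on a
reef flat. Defaults, chosen once as the study conditions the pipeline is
validated against:

| parameter | default | rationale |
|---|---|---|
| n_loci, alleles per locus | 9, 2–9 | typical resolving power of a small microsatellite panel for this taxon |
| fission_rate (per cold season) | 0.45 | field fission rates of 19–60% reported for dense populations |
| sexual_recruitment_rate (per warm season) | 10–15 recruits | rare MLGs a few percent of samples, turning over between years |
| mortality_rate (per season) | 0.08 | slow adult turnover; clones persist across years |
| founder_count / clone-size Dirichlet(0.3) | 8 | one to few dominant clones per site plus minor ones |
| founder_fis | -0.5 | the marked heterozygote excess characteristic of clonal populations |
| somatic_mutation_rate (per locus per fission) | 1e-4 | stepwise ±1 repeat; plants near-identical MLG pairs for the MLL logic |
| missing_rate (per individual-locus) | 0.0012 | reproduces ~98.9% fully complete 9-locus genotypes |
| growth | L_inf=342.24 mm, k=0.45/yr, t0=-0.25 yr | published von Bertalanffy fit for the species; fission halves body size, both halves regenerating |

Seasons alternate cold (fission) and warm (sexual recruitment), two per year;
rates are per season. Ramets are placed uniformly in the arena by default
(clonemates spatially mixed — adults of these species are mobile at the
plot scale), with an optional clustered placement (`clone_spread_m`) for
studying aggregation. Every record carries its true genet label.

`simulate_study` assembles the full survey design this pipeline targets:
three high-density sites (initial population 5,000 in an 80 m arena, two
nested-circular-plot stations of 64 samples at the first period, one at the
second, both seasons) and three low-density sites (initial population 900,
32 or 48 haphazard samples per date), two sampling periods two years apart,
about 1,450 records in total. Each site is simulated independently, so
clones never span sites. A one-year burn-in precedes the first sampling
date.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: shared clones between nearby sites on one reef,
larval dispersal between sites (sites are independent, so inter-site
differentiation is systematically high), genotyping artefacts other than
uniform missingness (no allele dropout or stutter), size-dependent fission,
and non-uniform spatial clustering of clonemates under the default
placement.

## Problem sizes used in validation

The shipped test suite and acceptance script run the full pipeline on the
~1,450-record simulated survey with 49–199 permutations and 199–999 null
replicates per population, and calibrate the statistical machinery on
100–1,000 randomized fixtures per property (metric axioms, binomial-tail and
variance-component oracles, percolation against exhaustive scan on all
graphs of up to 6 nodes, permutation-p uniformity over 200 replicates).
Production analyses should use the 10^3 permutations/replicates defaults.

## Known limitations

- The percolation threshold of published analyses depends on the distance
  normalization of the original network software, which is not recoverable
  from verbal descriptions; `Dpe` values are comparable within this package
  but not necessarily across tools.
- The F_IS-adjusted `P_sex` depends on which population's F_IS an MLG
  spanning several populations receives (plurality rule here); alternatives
  exist and can shift borderline flags.
- Jost's original D estimator is used; Chao's nearly unbiased variant can
  differ at very small sample sizes.
- `N_ap` depends on the comparison set supplied; the pipeline uses all other
  populations in the run.
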