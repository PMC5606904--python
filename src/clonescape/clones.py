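"""Clone identification from multilocus genotypes.

A *clone* is the set of individuals sharing one multilocus genotype (MLG).
Whether repeated copies of an MLG really are clonemates — rather than
independent products of sexual reproduction that collided on the same
genotype — is judged probabilistically:

* ``probability_of_identity`` (P_ID): chance that two random individuals share
  an MLG given the panel's allele frequencies; a panel-adequacy diagnostic.
* ``p_gen``: probability of one given multilocus genotype under random mating,
  optionally adjusted for per-locus departure from Hardy-Weinberg (F_IS).
* ``p_sex``: binomial upper tail — probability of seeing an MLG at least n
  times among N sexually produced individuals. MLGs whose F_IS-adjusted P_sex
  exceeds alpha are flagged as possibly multi-event.

Distinct MLGs separated by no more than a small number of mutation steps may
be somatic-mutation or scoring-error variants of one *multilocus lineage*
(MLL); ``mll_threshold`` reads the collapse threshold off the first gap in the
pairwise distance distribution and ``collapse_mll`` merges by single linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .genotype_io import LocusGenotype, SampleTable
from .networks import MLGDistanceMatrix
from .popgen import AlleleFrequencies, allele_frequencies, fis_per_locus

__all__ = [
    "MLG",
    "MLGCloneCall",
    "LocusPanelStats",
    "MLLPartition",
    "identify_mlgs",
    "probability_of_identity",
    "p_gen",
    "p_sex",
    "call_clones",
    "mll_threshold",
    "collapse_mll",
]


@dataclass(frozen=True)
class MLG:
    """A distinct multilocus genotype with its member individuals."""

    mlg_id: str
    genotype: tuple[LocusGenotype, ...]
    member_ids: tuple[str, ...]

    @property
    def n_copies(self) -> int:
        return len(self.member_ids)


def identify_mlgs(table: SampleTable) -> list[MLG]:
    """Group records by canonical multilocus genotype.

    Requires complete genotypes (run ``drop_incomplete`` first). Labels are
    deterministic: MLGs sorted by descending copy number, ties broken by the
    lexicographic order of the genotype vector, labelled MLG01, MLG02, ...
    """
    incomplete = [r.sample_id for r in table.records if not r.is_complete]
    if incomplete:
        raise ValueError(
            f"{len(incomplete)} records have missing data (e.g. "
            f"{incomplete[0]!r}); drop incomplete genotypes first"
        )
    groups: dict[tuple[LocusGenotype, ...], list[str]] = {}
    for rec in table.records:
        groups.setdefault(rec.genotype, []).append(rec.sample_id)

    def geno_key(genotype: tuple[LocusGenotype, ...]):
        return tuple((g.allele_a, g.allele_b) for g in genotype)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), geno_key(kv[0])))
    width = max(2, len(str(len(ordered))))
    return [
        MLG(
            mlg_id=f"MLG{i + 1:0{width}d}",
            genotype=genotype,
            member_ids=tuple(members),
        )
        for i, (genotype, members) in enumerate(ordered)
    ]


@dataclass
class LocusPanelStats:
    """Per-locus identity terms and the panel probability of identity."""

    per_locus: dict[str, float]
    p_id: float
    estimator: str


def probability_of_identity(
    freqs: AlleleFrequencies, estimator: str = "naive"
) -> LocusPanelStats:
    """Probability that two random individuals share the full multilocus
    genotype by chance.

    naive:    per-locus term  sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2
    unbiased: the small-sample correction of the same quantity (requires the
              per-locus gene-copy counts carried by ``freqs``)

    The panel P_ID is the product over loci.
    """
    if not freqs.freqs:
        raise ValueError("empty panel")
    per_locus: dict[str, float] = {}
    for locus, f in freqs.freqs.items():
        p = np.array(list(f.values()))
        if p.size == 0:
            raise ValueError(f"no alleles observed at locus {locus!r}")
        if estimator == "naive":
            hom = float((p**4).sum())
            outer = np.outer(p, p)
            het = float((2 * np.triu(outer, k=1) ** 2).sum() * 2)
            per_locus[locus] = hom + het
        elif estimator == "unbiased":
            n = freqs.n_copies[locus] // 2
            if n < 4:
                raise ValueError(
                    f"unbiased P_ID needs >= 4 individuals at {locus!r}"
                )
            a2 = float((p**2).sum())
            a3 = float((p**3).sum())
            a4 = float((p**4).sum())
            num = (
                n**3 * (2 * a2**2 - a4)
                - 2 * n**2 * (a3 + 2 * a2)
                + n * (9 * a2 + 2)
                - 6
            )
            per_locus[locus] = num / ((n - 1) * (n - 2) * (n - 3))
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        per_locus[locus] = min(1.0, per_locus[locus])
    p_id = float(np.prod(list(per_locus.values())))
    return LocusPanelStats(per_locus=per_locus, p_id=p_id, estimator=estimator)


def p_gen(
    genotype: Sequence[LocusGenotype],
    freqs: AlleleFrequencies,
    fis: dict[str, float] | None = None,
) -> float:
    """Probability of one multilocus genotype under random mating.

    Per locus: homozygous aa -> p_a^2 + F p_a (1 - p_a); heterozygous ab ->
    2 p_a p_b (1 - F); terms clamped to [0, 1]. ``fis=None`` gives the
    Hardy-Weinberg P_gen (F = 0 at every locus).
    """
    total = 1.0
    for locus, g in zip(freqs.locus_names, genotype):
        if g.is_missing:
            raise ValueError("p_gen requires a complete genotype")
        f = 0.0 if fis is None else fis.get(locus, 0.0)
        a, b = g.alleles()
        fl = freqs.freqs[locus]
        if a not in fl or b not in fl:
            raise ValueError(f"allele {a if a not in fl else b} absent at {locus!r}")
        if a == b:
            term = fl[a] ** 2 + f * fl[a] * (1 - fl[a])
        else:
            term = 2 * fl[a] * fl[b] * (1 - f)
        total *= float(np.clip(term, 0.0, 1.0))
    return total


def p_sex(pgen: float, n: int, N: int) -> float:
    """Probability that >= n of N sexually produced individuals carry a
    genotype of probability ``pgen`` (binomial upper tail, stable form)."""
    if not 0.0 <= pgen <= 1.0:
        raise ValueError(f"pgen must be in [0, 1], got {pgen}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > N:
        raise ValueError(f"n ({n}) cannot exceed N ({N})")
    return float(binom.sf(n - 1, N, pgen))


@dataclass
class MLGCloneCall:
    """Clone-call probabilities for one repeated MLG."""

    mlg_id: str
    n_copies: int
    p_gen: float
    p_sex: float
    p_gen_fis: float
    p_sex_fis: float
    distinct_events_flag: bool
    population_key: tuple[str, str, str, str]


def call_clones(table: SampleTable, alpha: float = 0.05) -> list[MLGCloneCall]:
    """P_sex clone calls for every MLG observed more than once.

    Allele frequencies are taken at ramet level over the whole table; the
    F_IS-adjusted call uses per-locus F_IS estimated in the population holding
    the plurality of the MLG's members. N in the binomial tail is the table
    size. MLGs with ``p_sex_fis > alpha`` are flagged: their copies may be
    distinct reproductive events rather than clonemates.
    """
    mlgs = identify_mlgs(table)
    freqs = allele_frequencies(table)
    pops = table.by_population()
    pop_fis = {key: fis_per_locus(sub) for key, sub in pops.items()}
    pop_of = {rec.sample_id: rec.population_key for rec in table.records}
    N = len(table)
    calls: list[MLGCloneCall] = []
    for mlg in mlgs:
        if mlg.n_copies < 2:
            continue
        keys = [pop_of[m] for m in mlg.member_ids]
        modal = max(set(keys), key=keys.count)
        pg = p_gen(mlg.genotype, freqs)
        pg_f = p_gen(mlg.genotype, freqs, fis=pop_fis[modal])
        ps = p_sex(pg, mlg.n_copies, N)
        ps_f = p_sex(pg_f, mlg.n_copies, N)
        calls.append(
            MLGCloneCall(
                mlg_id=mlg.mlg_id,
                n_copies=mlg.n_copies,
                p_gen=pg,
                p_sex=ps,
                p_gen_fis=pg_f,
                p_sex_fis=ps_f,
                distinct_events_flag=ps_f > alpha,
                population_key=modal,
            )
        )
    return calls


def mll_threshold(dist: MLGDistanceMatrix, atol: float = 1e-9) -> int:
    """Collapse threshold from the first gap of the pairwise distance
    distribution (unit bins of mutation steps).

    If one-step distances are present, the threshold is the top of the
    contiguous occupied run of unit bins starting at 1 (those small distances
    read as somatic mutations or scoring errors); otherwise it sits in the
    empty gap just below the smallest observed distance (d_min - 1). Fewer
    than two MLGs give 0.
    """
    if len(dist) < 2:
        return 0
    pairwise = dist.pairwise()
    steps = np.rint(pairwise).astype(int)
    if not np.allclose(pairwise, steps, atol=atol):
        raise ValueError("mll_threshold expects distances in integer mutation steps")
    occupied = set(int(s) for s in steps if s > 0)
    if not occupied:
        return 0
    d_min = min(occupied)
    if d_min >= 2:
        return d_min - 1
    t = 1
    while t + 1 in occupied:
        t += 1
    return t


@dataclass
class MLLPartition:
    """Assignment of MLGs to multilocus lineages at a distance threshold."""

    threshold: float
    assignment: dict[str, str]  # mlg_id -> mll_id

    @property
    def n_lineages(self) -> int:
        return len(set(self.assignment.values()))

    def lineages(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for mlg_id, mll_id in self.assignment.items():
            out.setdefault(mll_id, []).append(mlg_id)
        return out


def collapse_mll(
    mlgs: Sequence[MLG], dist: MLGDistanceMatrix, threshold: float
) -> MLLPartition:
    """Single-linkage components of the graph with edges at distance <= threshold."""
    ids = dist.mlg_ids
    if [m.mlg_id for m in mlgs] != ids:
        raise ValueError("mlgs and distance matrix must list the same ids in order")
    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if dist.values[i, j] <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots: dict[int, str] = {}
    assignment: dict[str, str] = {}
    width = max(2, len(str(n)))
    for i, mlg_id in enumerate(ids):
        r = find(i)
        if r not in roots:
            roots[r] = f"MLL{len(roots) + 1:0{width}d}"
        assignment[mlg_id] = roots[r]
    return MLLPartition(threshold=threshold, assignment=assignment)
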