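"""Classical population-genetic summaries and differentiation.

Per-population allele frequencies, mean allelic number (N_a), private alleles
(N_ap), observed and Nei-unbiased expected heterozygosity, the Weir-Cockerham
within-population inbreeding coefficient f (F_IS) with a permutation test for
Hardy-Weinberg departure, and pairwise differentiation: Weir-Cockerham theta
(F_ST) via variance components and Jost's D_est with Nei-Chesser unbiased
heterozygosities. All statistics can be computed at *ramet* level (every
individual) or *genet* level (one representative per distinct multilocus
genotype), the distinction that matters in partially clonal populations.

Missing single-locus genotypes are skipped locus-wise, so tables that have not
been filtered to complete genotypes are still summarizable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .genotype_io import MISSING, LocusGenotype, SampleRecord, SampleTable

__all__ = [
    "AlleleFrequencies",
    "DiversitySummary",
    "PairwiseDifferentiation",
    "allele_frequencies",
    "fis_per_locus",
    "diversity_summary",
    "wc_fst",
    "jost_dest",
    "pairwise_differentiation",
]

Level = Literal["ramet", "genet"]


def dedupe_genets(table: SampleTable) -> SampleTable:
    """One representative record per distinct multilocus genotype."""
    seen: dict[tuple, SampleRecord] = {}
    for rec in table.records:
        seen.setdefault(rec.genotype, rec)
    return SampleTable(table.panel, list(seen.values()))


def _level_table(table: SampleTable, level: Level) -> SampleTable:
    if level == "genet":
        return dedupe_genets(table)
    if level != "ramet":
        raise ValueError(f"level must be 'ramet' or 'genet', got {level!r}")
    return table


@dataclass
class AlleleFrequencies:
    """Per-locus allele relative frequencies with gene-copy sample sizes."""

    freqs: dict[str, dict[int, float]]
    n_copies: dict[str, int]
    n_individuals: int

    @property
    def locus_names(self) -> list[str]:
        return list(self.freqs)

    def validate(self) -> None:
        for locus, f in self.freqs.items():
            total = sum(f.values())
            if f and not np.isclose(total, 1.0):
                raise ValueError(f"frequencies at {locus!r} sum to {total}, not 1")


def allele_frequencies(table: SampleTable, level: Level = "ramet") -> AlleleFrequencies:
    """Count alleles over 2N gene copies per locus (missing genotypes skipped)."""
    if not table.records:
        raise ValueError("cannot compute allele frequencies of an empty table")
    table = _level_table(table, level)
    freqs: dict[str, dict[int, float]] = {}
    n_copies: dict[str, int] = {}
    for j, locus in enumerate(table.panel):
        counts: dict[int, int] = {}
        for rec in table.records:
            g = rec.genotype[j]
            if g.is_missing:
                continue
            a, b = g.alleles()
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        n_copies[locus.name] = total
        freqs[locus.name] = (
            {al: c / total for al, c in sorted(counts.items())} if total else {}
        )
    return AlleleFrequencies(freqs=freqs, n_copies=n_copies, n_individuals=len(table))


# ---------------------------------------------------------------------------
# per-locus heterozygosities and F_IS
# ---------------------------------------------------------------------------


def _locus_counts(table: SampleTable, j: int) -> tuple[int, int, dict[int, float]]:
    """(n individuals typed, n heterozygotes, allele freqs) at locus index j."""
    n = het = 0
    counts: dict[int, int] = {}
    for rec in table.records:
        g = rec.genotype[j]
        if g.is_missing:
            continue
        n += 1
        if g.is_heterozygous:
            het += 1
        a, b = g.alleles()
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = sum(counts.values())
    return n, het, {al: c / total for al, c in counts.items()} if total else {}


def observed_heterozygosity(table: SampleTable) -> dict[str, float]:
    out = {}
    for j, locus in enumerate(table.panel):
        n, het, _ = _locus_counts(table, j)
        out[locus.name] = het / n if n else float("nan")
    return out


def nei_unbiased_he(table: SampleTable) -> dict[str, float]:
    """Nei's unbiased expected heterozygosity 2N/(2N-1) * (1 - sum p^2)."""
    out = {}
    for j, locus in enumerate(table.panel):
        n, _, p = _locus_counts(table, j)
        if n < 1:
            out[locus.name] = float("nan")
            continue
        raw = 1.0 - sum(v * v for v in p.values())
        out[locus.name] = (2 * n / (2 * n - 1)) * raw if n > 0 else float("nan")
    return out


def fis_per_locus(table: SampleTable, clamp: float = 0.9999) -> dict[str, float]:
    """Quick per-locus inbreeding estimate 1 - H_O/H_E, clamped to (-1, 1).

    Used to adjust single-genotype probabilities (P_gen) for Hardy-Weinberg
    departure; monomorphic loci get 0 (the genotype probability is 1 there
    regardless).
    """
    ho = observed_heterozygosity(table)
    he = nei_unbiased_he(table)
    out = {}
    for name in ho:
        if not he[name] or np.isnan(he[name]) or he[name] == 0:
            out[name] = 0.0
        else:
            out[name] = float(np.clip(1.0 - ho[name] / he[name], -clamp, clamp))
    return out


def _wc_within_components(table: SampleTable) -> tuple[float, float]:
    """Weir-Cockerham within-population variance components (sum b, sum c).

    Per locus and allele A, with n typed individuals, p the allele frequency
    and h the proportion of individuals heterozygous for A:

        b = n/(n-1) * [ p(1-p) - (2n-1)/(4n) * h ]
        c = h/2

    f = 1 - sum(c) / sum(b + c), summed over alleles and loci.
    """
    sum_b = sum_c = 0.0
    for j, _ in enumerate(table.panel):
        n = 0
        het_count: dict[int, int] = {}
        counts: dict[int, int] = {}
        for rec in table.records:
            g = rec.genotype[j]
            if g.is_missing:
                continue
            n += 1
            a, b = g.alleles()
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
            if a != b:
                het_count[a] = het_count.get(a, 0) + 1
                het_count[b] = het_count.get(b, 0) + 1
        if n < 2 or len(counts) < 2:
            continue
        total = 2 * n
        for allele, c in counts.items():
            p = c / total
            h = het_count.get(allele, 0) / n
            sum_b += (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            sum_c += h / 2
    return sum_b, sum_c


def multilocus_fis(table: SampleTable) -> float:
    """Multilocus Weir-Cockerham f (ratio of summed variance components)."""
    b, c = _wc_within_components(table)
    denom = b + c
    if denom == 0:
        return float("nan")
    return 1.0 - c / denom


def _hwe_permutation(table: SampleTable, n_perm: int, rng: np.random.Generator) -> float:
    """Permute alleles among individuals within each locus; two-sided on |f|."""
    obs = multilocus_fis(table)
    if np.isnan(obs):
        return float("nan")
    # stack per-locus allele pools once
    pools: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for j, _ in enumerate(table.panel):
        alleles = []
        mask = []
        for rec in table.records:
            g = rec.genotype[j]
            mask.append(not g.is_missing)
            if not g.is_missing:
                alleles += list(g.alleles())
        pools.append(np.array(alleles))
        masks.append(np.array(mask))
    hits = 0
    for _ in range(n_perm):
        recs = []
        perms = [rng.permutation(pool) for pool in pools]
        cursors = [0] * len(pools)
        for i, rec in enumerate(table.records):
            geno = []
            for j in range(len(table.panel)):
                if masks[j][i]:
                    k = cursors[j]
                    geno.append(
                        LocusGenotype(int(perms[j][k]), int(perms[j][k + 1]))
                    )
                    cursors[j] += 2
                else:
                    geno.append(MISSING)
            recs.append(
                SampleRecord(sample_id=rec.sample_id, site=rec.site, genotype=tuple(geno))
            )
        perm_f = multilocus_fis(SampleTable(table.panel, recs))
        if not np.isnan(perm_f) and abs(perm_f) >= abs(obs):
            hits += 1
    return (hits + 1) / (n_perm + 1)


@dataclass
class DiversitySummary:
    """Per-population diversity indices (Table-2 style)."""

    population_key: tuple[str, str, str, str]
    n: int
    n_a: float
    n_ap: float
    h_o: float
    h_o_se: float
    h_e: float
    h_e_se: float
    f_is: float
    hwe_p: float


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    arr = np.array([v for v in values if not np.isnan(v)], dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    se = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
    return float(arr.mean()), float(se)


def diversity_summary(
    pop: SampleTable,
    comparison_set: Iterable[SampleTable] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> DiversitySummary:
    """Diversity indices of one population.

    ``comparison_set`` holds the *other* populations used to score private
    alleles (N_ap = mean per locus of alleles found here and nowhere else).
    """
    if len(pop) < 2:
        raise ValueError("diversity_summary requires at least 2 individuals")
    rng = np.random.default_rng(seed)
    ho = observed_heterozygosity(pop)
    he = nei_unbiased_he(pop)
    own = allele_frequencies(pop)

    n_a = float(np.mean([len(own.freqs[l]) for l in own.freqs]))

    if comparison_set:
        others: set[tuple[str, int]] = set()
        for other in comparison_set:
            of = allele_frequencies(other)
            for locus, f in of.freqs.items():
                others.update((locus, al) for al in f)
        private = [
            sum((locus, al) not in others for al in f)
            for locus, f in own.freqs.items()
        ]
        n_ap = float(np.mean(private))
    else:
        n_ap = float("nan")

    h_o, h_o_se = _mean_se(list(ho.values()))
    h_e, h_e_se = _mean_se(list(he.values()))
    f_is = multilocus_fis(pop)
    hwe_p = (
        _hwe_permutation(pop, n_perm, rng) if not np.isnan(f_is) else float("nan")
    )
    return DiversitySummary(
        population_key=pop.records[0].population_key,
        n=len(pop),
        n_a=n_a,
        n_ap=n_ap,
        h_o=h_o,
        h_o_se=h_o_se,
        h_e=h_e,
        h_e_se=h_e_se,
        f_is=f_is,
        hwe_p=hwe_p,
    )


# ---------------------------------------------------------------------------
# pairwise differentiation
# ---------------------------------------------------------------------------


def _genotype_codes(tables: Sequence[SampleTable]) -> list[list[np.ndarray]]:
    """Integer-coded allele arrays [pop][locus] of shape (n_typed, 2)."""
    panel = tables[0].panel
    out: list[list[np.ndarray]] = []
    for t in tables:
        per_locus = []
        for j, _ in enumerate(panel):
            rows = [
                rec.genotype[j].alleles()
                for rec in t.records
                if not rec.genotype[j].is_missing
            ]
            per_locus.append(np.array(rows, dtype=np.int64).reshape(-1, 2))
        out.append(per_locus)
    return out


def _theta_components(pop_loci: Sequence[Sequence[np.ndarray]]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components summed over alleles and loci."""
    r = len(pop_loci)
    n_loci = len(pop_loci[0])
    A = B = C = 0.0
    for j in range(n_loci):
        mats = [pop_loci[i][j] for i in range(r)]
        ns = np.array([m.shape[0] for m in mats], dtype=float)
        if np.any(ns < 1):
            continue
        alleles = np.unique(np.concatenate([m.ravel() for m in mats]))
        if alleles.size < 2:
            continue
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        if nc == 0:
            continue
        for allele in alleles:
            p_i = np.array([np.mean(m == allele) for m in mats])
            h_i = np.array(
                [np.mean((m == allele).sum(axis=1) == 1) for m in mats]
            )
            pbar = (ns * p_i).sum() / (r * nbar)
            s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ns * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - s2 * (r - 1) / r
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2
            A += a
            B += b
            C += c
    return A, B, C


def wc_theta(tables: Sequence[SampleTable]) -> float:
    """Multilocus, multiallelic Weir-Cockerham theta over >= 2 populations."""
    codes = _genotype_codes(tables)
    a, b, c = _theta_components(codes)
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return a / denom


def _jost_d_locus(mats: Sequence[np.ndarray]) -> float:
    """Jost's D at one locus with Nei-Chesser unbiased H_S/H_T (r pops)."""
    r = len(mats)
    ns = np.array([m.shape[0] for m in mats], dtype=float)
    if np.any(ns < 1):
        return float("nan")
    n_harm = r / (1.0 / ns).sum()
    alleles = np.unique(np.concatenate([m.ravel() for m in mats]))
    if alleles.size < 2:
        return float("nan")
    p = np.array([[np.mean(m == al) for al in alleles] for m in mats])  # (r, k)
    h_o = float(
        np.mean([np.mean((m[:, 0] != m[:, 1])) for m in mats])
    )
    hs_raw = 1.0 - float(np.mean((p**2).sum(axis=1)))
    hs = (n_harm / (n_harm - 1)) * (hs_raw - h_o / (2 * n_harm))
    pbar = p.mean(axis=0)
    ht_raw = 1.0 - float((pbar**2).sum())
    ht = ht_raw + hs / (r * n_harm) - h_o / (2 * r * n_harm)
    if hs >= 1.0:
        return float("nan")
    return ((ht - hs) / (1.0 - hs)) * (r / (r - 1))


def jost_d(tables: Sequence[SampleTable]) -> float:
    """Jost's D_est averaged arithmetically over loci (nan loci skipped)."""
    codes = _genotype_codes(tables)
    n_loci = len(codes[0])
    vals = []
    for j in range(n_loci):
        d = _jost_d_locus([codes[i][j] for i in range(len(codes))])
        if not np.isnan(d):
            vals.append(d)
    if not vals:
        warnings.warn("no informative loci for Jost's D")
        return float("nan")
    return float(np.mean(vals))


@dataclass
class PairwiseDifferentiation:
    """F_ST and D_est between one population pair, with permutation p-values."""

    pop_a: tuple[str, str, str, str]
    pop_b: tuple[str, str, str, str]
    fst: float
    fst_p: float
    dest: float
    dest_p: float
    level: Level
    n_perm: int
    seed: int | None


def _permute_pair(
    popA: SampleTable,
    popB: SampleTable,
    statistic,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    obs = statistic([popA, popB])
    if np.isnan(obs) or n_perm <= 0:
        return obs, float("nan")
    pooled = popA.records + popB.records
    nA = len(popA)
    hits = 0
    panel = popA.panel
    idx = np.arange(len(pooled))
    for _ in range(n_perm):
        rng.shuffle(idx)
        a = SampleTable(panel, [pooled[i] for i in idx[:nA]])
        b = SampleTable(panel, [pooled[i] for i in idx[nA:]])
        if statistic([a, b]) >= obs:
            hits += 1
    return obs, (hits + 1) / (n_perm + 1)


def wc_fst(
    popA: SampleTable,
    popB: SampleTable,
    n_perm: int = 1000,
    seed: int | None = None,
    level: Level = "ramet",
) -> PairwiseDifferentiation:
    """Weir-Cockerham theta between two populations, permutation-tested."""
    return _pair_stats(popA, popB, n_perm, seed, level, do_fst=True, do_dest=False)


def jost_dest(
    popA: SampleTable,
    popB: SampleTable,
    n_perm: int = 1000,
    seed: int | None = None,
    level: Level = "ramet",
) -> PairwiseDifferentiation:
    """Jost's D_est between two populations, permutation-tested."""
    return _pair_stats(popA, popB, n_perm, seed, level, do_fst=False, do_dest=True)


def pairwise_differentiation(
    popA: SampleTable,
    popB: SampleTable,
    n_perm: int = 1000,
    seed: int | None = None,
    level: Level = "ramet",
) -> PairwiseDifferentiation:
    """Both differentiation indices for one population pair."""
    return _pair_stats(popA, popB, n_perm, seed, level, do_fst=True, do_dest=True)


def _pair_stats(
    popA: SampleTable,
    popB: SampleTable,
    n_perm: int,
    seed: int | None,
    level: Level,
    do_fst: bool,
    do_dest: bool,
) -> PairwiseDifferentiation:
    if len(popA) < 2 or len(popB) < 2:
        raise ValueError("differentiation requires >= 2 individuals per population")
    a = _level_table(popA, level)
    b = _level_table(popB, level)
    rng = np.random.default_rng(seed)
    fst = fst_p = dest = dest_p = float("nan")
    if do_fst:
        fst, fst_p = _permute_pair(a, b, wc_theta, n_perm, rng)
        if np.isnan(fst):
            warnings.warn("no shared polymorphism: theta undefined")
    if do_dest:
        dest, dest_p = _permute_pair(a, b, jost_d, n_perm, rng)
    return PairwiseDifferentiation(
        pop_a=popA.records[0].population_key,
        pop_b=popB.records[0].population_key,
        fst=fst,
        fst_p=fst_p,
        dest=dest,
        dest_p=dest_p,
        level=level,
        n_perm=n_perm,
        seed=seed,
    )
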