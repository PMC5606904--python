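"""Per-population clonal diversity indices.

Three summaries of how a sample of N individuals partitions into G clones:

* clonal richness ``R = (G - 1) / (N - 1)`` — 0 for a monoclonal sample, 1
  when every individual is genetically distinct;
* Pielou's evenness ``J' = H' / ln G`` of the clone-size distribution;
* the Pareto exponent ``beta`` of the inverse cumulative clone-size
  distribution (small beta = dominance by few large clones), estimated as
  minus the OLS slope of ln N(>=X) on ln X over the distinct clone sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import SampleTable

__all__ = [
    "CloneSummary",
    "clonal_richness",
    "pielou_evenness",
    "pareto_beta",
    "clone_sizes",
]


def clonal_richness(N: int, G: int) -> float:
    """(G - 1)/(N - 1); defined as 0 for N = 1."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 1 <= G <= N:
        raise ValueError(f"G must be in [1, N]; got G={G}, N={N}")
    if N == 1:
        return 0.0
    return (G - 1) / (N - 1)


def pielou_evenness(clone_sizes: Sequence[int]) -> float:
    """Shannon evenness H'/ln(G) of clone sizes; NaN for a single clone."""
    sizes = np.asarray(clone_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("clone_sizes must be non-empty")
    if (sizes <= 0).any():
        raise ValueError("clone sizes must be positive")
    if sizes.size == 1:
        return float("nan")
    p = sizes / sizes.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(sizes.size))


def pareto_beta(clone_sizes: Sequence[int]) -> float:
    """Power-law exponent of the inverse cumulative clone-size distribution.

    For each distinct size X, N(>=X) counts clones at least that large; beta
    is -1 times the OLS slope of ln N(>=X) on ln X (natural logs, sizes
    unbinned, ties collapsed to one point). A single distinct size gives NaN.
    """
    sizes = np.asarray(clone_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("clone_sizes must be non-empty")
    if (sizes <= 0).any():
        raise ValueError("clone sizes must be positive")
    distinct = np.unique(sizes)
    if distinct.size < 2:
        return float("nan")
    n_geq = np.array([(sizes >= x).sum() for x in distinct], dtype=float)
    slope = np.polyfit(np.log(distinct), np.log(n_geq), 1)[0]
    return float(-slope)


def clone_sizes(table: SampleTable) -> list[int]:
    """Clone (MLG) copy numbers of a complete-genotype table, descending."""
    from .clones import identify_mlgs

    return [m.n_copies for m in identify_mlgs(table)]


@dataclass
class CloneSummary:
    """Clonal-structure indices of one population (Table-2 style)."""

    population_key: tuple[str, str, str, str]
    n: int
    g: int
    r: float
    j_prime: float
    beta: float
    a_c: float = float("nan")
    ac_p: float = float("nan")
    e_e: float = float("nan")
    ee_p: float = float("nan")


def clone_summary(
    table: SampleTable,
    n_perm: int = 1000,
    seed: int | None = None,
    spatial: bool = True,
) -> CloneSummary:
    """All clonal indices of one population; spatial indices (A_c, E_e) are
    computed when the records carry coordinates."""
    sizes = clone_sizes(table)
    N = len(table)
    G = len(sizes)
    summary = CloneSummary(
        population_key=table.records[0].population_key,
        n=N,
        g=G,
        r=clonal_richness(N, G),
        j_prime=pielou_evenness(sizes),
        beta=pareto_beta(sizes),
    )
    if spatial and all(r.has_coordinates for r in table.records) and G >= 2 and N >= 3:
        from .spatial import aggregation_index, edge_effect

        ac = aggregation_index(table, n_perm=n_perm, seed=seed)
        ee = edge_effect(table, n_perm=n_perm, seed=seed)
        summary.a_c, summary.ac_p = ac.value, ac.p_value
        summary.e_e, summary.ee_p = ee.value, ee.p_value
    return summary
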