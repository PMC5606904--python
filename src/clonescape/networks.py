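"""Stepwise-mutation genetic distances and genotype networks.

The distance between two diploid multilocus genotypes follows Rozenfeld's
construction for microsatellites: at each locus the two allele pairs are
matched in the way that minimizes the total absolute difference in repeat
units (allele size divided by the locus motif length), and locus contributions
are summed. Under a strict stepwise mutation model a single somatic mutation
therefore moves a genotype by exactly one.

Networks take MLGs as nodes and pairwise distances as weighted links. Scanning
thresholds downward from the fully connected graph, the percolation threshold
Dpe is the smallest distance at which the network is still a single connected
component; just below it the network fragments into its first clusters, the
coarsest signal of restricted gene flow. The mean unweighted clustering
coefficient <CC> summarizes the cohesion of the thresholded network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import LocusDef, LocusGenotype

__all__ = [
    "MLGDistanceMatrix",
    "NetworkSummary",
    "rozenfeld_distance",
    "distance_matrix",
    "build_network",
    "percolation_threshold",
    "clustering_coefficient",
]


def rozenfeld_distance(
    g1: Sequence[LocusGenotype],
    g2: Sequence[LocusGenotype],
    panel: Sequence[LocusDef],
) -> float:
    """Stepwise-mutation distance between two complete multilocus genotypes.

    Per locus: min over the two allele pairings of the summed |differences|
    in repeat units; total: sum over loci. A one-step somatic mutation at one
    locus yields distance 1.
    """
    if not (len(g1) == len(g2) == len(panel)):
        raise ValueError("genotypes and panel must have the same locus count")
    total = 0.0
    for ga, gb, locus in zip(g1, g2, panel):
        if ga.is_missing or gb.is_missing:
            raise ValueError("distances require complete genotypes")
        a1, a2 = (x / locus.motif_length for x in ga.alleles())
        b1, b2 = (x / locus.motif_length for x in gb.alleles())
        total += min(abs(a1 - b1) + abs(a2 - b2), abs(a1 - b2) + abs(a2 - b1))
    return total


@dataclass
class MLGDistanceMatrix:
    """Symmetric pairwise distance matrix over an ordered list of MLG ids."""

    mlg_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.mlg_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.mlg_ids)

    def pairwise(self) -> np.ndarray:
        """Condensed upper-triangle distances (no diagonal)."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]


def distance_matrix(mlgs: Sequence, panel: Sequence[LocusDef]) -> MLGDistanceMatrix:
    """All pairwise Rozenfeld distances between objects with .mlg_id/.genotype."""
    n = len(mlgs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = rozenfeld_distance(mlgs[i].genotype, mlgs[j].genotype, panel)
            values[i, j] = values[j, i] = d
    return MLGDistanceMatrix([m.mlg_id for m in mlgs], values)


def build_network(
    dist: MLGDistanceMatrix,
    threshold: float | None = None,
    node_attrs: Mapping[str, Mapping] | None = None,
) -> nx.Graph:
    """Genotype network: complete graph if ``threshold`` is None, else only
    links with distance <= threshold. Node attributes (e.g. n_copies, site)
    are attached when supplied."""
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(dist.mlg_ids)
    n = len(dist)
    for i in range(n):
        for j in range(i + 1, n):
            d = dist.values[i, j]
            if threshold is None or d <= threshold:
                g.add_edge(dist.mlg_ids[i], dist.mlg_ids[j], distance=float(d))
    if node_attrs:
        for key, attrs in node_attrs.items():
            g.nodes[key].update(attrs)
    return g


def clustering_coefficient(network: nx.Graph) -> float:
    """Mean unweighted local clustering (nodes of degree < 2 contribute 0)."""
    if network.number_of_nodes() == 0:
        return float("nan")
    return float(nx.average_clustering(network))


@dataclass
class NetworkSummary:
    """Percolation diagnostics of a genotype network."""

    dpe: float
    cc: float
    n_components: int
    components: list[frozenset]
    thresholds: np.ndarray
    giant_fraction: np.ndarray
    susceptibility: np.ndarray

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "giant_fraction": self.giant_fraction,
                "susceptibility": self.susceptibility,
            }
        )


def percolation_threshold(dist: MLGDistanceMatrix) -> NetworkSummary:
    """Scan thresholds over the distance values and locate the percolation
    threshold Dpe: the smallest candidate keeping the network in one connected
    component. ``components`` holds the clusters at the next threshold below
    Dpe; the susceptibility curve (mean size of non-giant components) is
    reported for the alternative peak-based convention."""
    n = len(dist)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return NetworkSummary(
            dpe=0.0,
            cc=0.0,
            n_components=1,
            components=[frozenset(dist.mlg_ids)],
            thresholds=np.array([0.0]),
            giant_fraction=np.array([1.0]),
            susceptibility=np.array([0.0]),
        )
    candidates = np.unique(dist.pairwise())
    giant = np.empty(candidates.size)
    susc = np.empty(candidates.size)
    comps_at: list[list[set]] = []
    for k, t in enumerate(candidates):
        g = build_network(dist, threshold=float(t))
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        comps_at.append(comps)
        giant[k] = len(comps[0]) / n
        rest = [len(c) for c in comps[1:]]
        susc[k] = float(np.mean(rest)) if rest else 0.0
    connected = np.nonzero(giant == 1.0)[0]
    # the complete graph is always connected, so the largest candidate qualifies
    k_dpe = int(connected.min())
    dpe = float(candidates[k_dpe])
    if k_dpe == 0:
        clusters = [frozenset(dist.mlg_ids)]
    else:
        clusters = [frozenset(c) for c in comps_at[k_dpe - 1]]
    cc = clustering_coefficient(build_network(dist, threshold=dpe))
    return NetworkSummary(
        dpe=dpe,
        cc=cc,
        n_components=len(clusters),
        components=clusters,
        thresholds=candidates,
        giant_fraction=giant,
        susceptibility=susc,
    )
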