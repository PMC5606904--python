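"""Spatial arrangement of clonemates within a sampling plot.

Two permutation-tested indices, computed on a population whose records carry
planar coordinates (metres relative to the station centre):

* **Aggregation** ``A_c = (P_sg - P_sp) / (1 - P_sp)``, where P_sg is the
  fraction of individuals whose nearest geographic neighbour is a clonemate
  and P_sp the probability that two random individuals are clonemates
  (sum n_i (n_i - 1) / (N (N - 1))). Positive values mean clonemates sit
  closer together than expected; significance by permuting clone labels over
  the fixed coordinates.
* **Edge effect** ``E_e = (d_u - d_all) / d_all``, comparing the mean
  distance-to-centre of individuals bearing unique (single-copy) genotypes
  with that of all individuals. Positive values mean new genotypes concentrate
  at the plot rim; significance by permuting which individuals count as
  unique.

Both permutation p-values are one-sided with the +1 correction, so the
observed statistic is always included and p is never 0. Because A_c is a
discrete statistic (P_sg is a fraction over N individuals), permutations tie
with the observed value often; ties are broken randomly (a uniform draw over
the tie block, seeded by the same RNG), which makes the null distribution of
p exactly uniform on {1/(n+1), ..., 1} under label exchangeability instead of
conservative. With no ties this reduces to (#{perm >= obs} + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .genotype_io import SampleTable

__all__ = ["SpatialPermutationResult", "aggregation_index", "edge_effect"]


@dataclass
class SpatialPermutationResult:
    statistic_name: str
    value: float
    p_value: float
    n_perm: int
    seed: int | None
    metadata: dict = field(default_factory=dict)


def _perm_p(obs: float, perm_values: np.ndarray, rng: np.random.Generator) -> float:
    """One-sided permutation p with random tie-breaking (see module docstring)."""
    strict = int((perm_values > obs).sum())
    ties = int((perm_values == obs).sum())
    u = int(rng.integers(0, ties + 1))
    return (strict + u + 1) / (perm_values.size + 1)


def _coords_and_labels(table: SampleTable) -> tuple[np.ndarray, np.ndarray]:
    from .clones import identify_mlgs

    if not all(r.has_coordinates for r in table.records):
        raise ValueError("spatial indices require coordinates on every record")
    xy = np.array([(r.x, r.y) for r in table.records], dtype=float)
    mlgs = identify_mlgs(table)
    label_of = {}
    for k, m in enumerate(mlgs):
        for sid in m.member_ids:
            label_of[sid] = k
    labels = np.array([label_of[r.sample_id] for r in table.records])
    return xy, labels


def _nearest_neighbour(table: SampleTable, xy: np.ndarray) -> np.ndarray:
    """Index of each sample's nearest neighbour; ties broken by sample_id
    order after the distance sort. Coincident points are valid neighbours."""
    d = cdist(xy, xy)
    np.fill_diagonal(d, np.inf)
    ids = [r.sample_id for r in table.records]
    order = np.argsort(np.array(ids))  # rank by sample_id for tie-breaks
    rank = np.empty(len(ids))
    rank[order] = np.arange(len(ids))
    nn = np.empty(len(ids), dtype=int)
    for i in range(len(ids)):
        row = d[i]
        best = np.flatnonzero(row == row.min())
        nn[i] = best[np.argmin(rank[best])]
    return nn


def aggregation_index(
    table: SampleTable, n_perm: int = 1000, seed: int | None = None
) -> SpatialPermutationResult:
    """Clonemate aggregation A_c with a one-sided label-permutation test."""
    if len(table) < 3:
        raise ValueError("aggregation index requires >= 3 samples")
    xy, labels = _coords_and_labels(table)
    _, counts = np.unique(labels, return_counts=True)
    meta = {"definition": "A_c=(P_sg-P_sp)/(1-P_sp); P_sg via nearest neighbour"}
    if counts.size < 2:
        return SpatialPermutationResult(
            "A_c", float("nan"), float("nan"), n_perm, seed, meta
        )
    N = len(labels)
    p_sp = float((counts * (counts - 1)).sum() / (N * (N - 1)))
    nn = _nearest_neighbour(table, xy)

    def statistic(lab: np.ndarray) -> float:
        p_sg = float(np.mean(lab[nn] == lab))
        return (p_sg - p_sp) / (1.0 - p_sp)

    obs = statistic(labels)
    rng = np.random.default_rng(seed)
    perm = np.array([statistic(rng.permutation(labels)) for _ in range(n_perm)])
    return SpatialPermutationResult(
        "A_c", obs, _perm_p(obs, perm, rng), n_perm, seed, meta
    )


def edge_effect(
    table: SampleTable,
    centre: tuple[float, float] = (0.0, 0.0),
    n_perm: int = 1000,
    seed: int | None = None,
) -> SpatialPermutationResult:
    """Edge effect E_e of unique genotypes, one-sided permutation test.

    The default centre (0, 0) is the station plot centre of the nested
    circular sampling design.
    """
    if len(table) < 3:
        raise ValueError("edge effect requires >= 3 samples")
    xy, labels = _coords_and_labels(table)
    _, counts = np.unique(labels, return_counts=True)
    meta = {
        "definition": "E_e=(d_u-d_all)/d_all; d = distance to plot centre",
        "centre": centre,
    }
    unique_labels = {k for k, c in enumerate(counts) if c == 1}
    is_unique = np.array([l in unique_labels for l in labels])
    if counts.size < 2 or not is_unique.any():
        return SpatialPermutationResult(
            "E_e", float("nan"), float("nan"), n_perm, seed, meta
        )
    d = np.hypot(xy[:, 0] - centre[0], xy[:, 1] - centre[1])
    d_all = float(d.mean())
    if d_all == 0:
        return SpatialPermutationResult("E_e", 0.0, 1.0, n_perm, seed, meta)

    def statistic(mask: np.ndarray) -> float:
        return (float(d[mask].mean()) - d_all) / d_all

    obs = statistic(is_unique)
    rng = np.random.default_rng(seed)
    k = int(is_unique.sum())
    perm = np.empty(n_perm)
    for b in range(n_perm):
        mask = np.zeros(len(d), dtype=bool)
        mask[rng.choice(len(d), size=k, replace=False)] = True
        perm[b] = statistic(mask)
    return SpatialPermutationResult(
        "E_e", obs, _perm_p(obs, perm, rng), n_perm, seed, meta
    )
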