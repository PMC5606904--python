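"""Shared fixtures: hand-built and randomly generated genotype tables."""

from __future__ import annotations

import numpy as np
import pytest

from clonescape.genotype_io import (
    LocusDef,
    LocusGenotype,
    SampleRecord,
    SampleTable,
)


def make_panel(n_loci: int = 3, motif: int = 1) -> list[LocusDef]:
    return [LocusDef(f"L{j + 1}", motif_length=motif) for j in range(n_loci)]


def make_record(
    sample_id: str,
    alleles: list[tuple[int | None, int | None]],
    panel: list[LocusDef],
    **meta,
) -> SampleRecord:
    return SampleRecord(
        sample_id=sample_id,
        site=meta.pop("site", "A"),
        genotype=tuple(LocusGenotype(a, b) for a, b in alleles),
        **meta,
    )


def make_random_table(
    seed: int = 0,
    n: int = 20,
    n_loci: int = 4,
    n_alleles: int = 5,
    with_meta: bool = True,
    missing_rate: float = 0.0,
) -> SampleTable:
    rng = np.random.default_rng(seed)
    panel = make_panel(n_loci)
    records = []
    for i in range(n):
        geno = []
        for _ in range(n_loci):
            if missing_rate and rng.random() < missing_rate:
                geno.append(LocusGenotype(None, None))
            else:
                a, b = rng.integers(100, 100 + n_alleles, size=2)
                geno.append(LocusGenotype(int(a), int(b)))
        meta = {}
        if with_meta:
            meta = dict(
                site=f"S{i % 2 + 1}",
                station=f"st{i % 2 + 1}",
                season="cold" if i % 2 else "warm",
                period="T0",
                x=float(rng.uniform(-40, 40)),
                y=float(rng.uniform(-40, 40)),
                size_cm=float(rng.uniform(5, 25)),
            )
        records.append(
            SampleRecord(sample_id=f"ind{i:03d}", genotype=tuple(geno), **meta)
            if with_meta
            else SampleRecord(sample_id=f"ind{i:03d}", site="A", genotype=tuple(geno))
        )
    return SampleTable(panel, records)


def clone_table(
    clone_sizes: list[int],
    n_loci: int = 5,
    seed: int = 0,
    site: str = "A",
    coords: np.ndarray | None = None,
) -> SampleTable:
    """Table with one distinct random genotype per clone, repeated to size."""
    rng = np.random.default_rng(seed)
    panel = make_panel(n_loci)
    genotypes = set()
    while len(genotypes) < len(clone_sizes):
        g = tuple(
            tuple(sorted(rng.integers(100, 112, size=2).tolist()))
            for _ in range(n_loci)
        )
        genotypes.add(g)
    records = []
    i = 0
    for size, g in zip(clone_sizes, sorted(genotypes)):
        for _ in range(size):
            xy = {} if coords is None else {"x": float(coords[i, 0]), "y": float(coords[i, 1])}
            records.append(
                SampleRecord(
                    sample_id=f"s{i:03d}",
                    site=site,
                    genotype=tuple(LocusGenotype(a, b) for a, b in g),
                    **xy,
                )
            )
            i += 1
    return SampleTable(panel, records)


@pytest.fixture
def small_table() -> SampleTable:
    """Two populations, three loci, including one repeated genotype."""
    panel = make_panel(3)
    rows = [
        ("a1", "A", [(100, 102), (120, 120), (131, 135)]),
        ("a2", "A", [(102, 100), (120, 120), (135, 131)]),  # same MLG as a1
        ("a3", "A", [(100, 100), (120, 122), (131, 131)]),
        ("b1", "B", [(104, 102), (122, 122), (135, 135)]),
    ]
    records = [
        SampleRecord(
            sample_id=sid,
            site=site,
            genotype=tuple(LocusGenotype(a, b) for a, b in geno),
        )
        for sid, site, geno in rows
    ]
    return SampleTable(panel, records)
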