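"""Data model and readers/writers for codominant diploid genotype tables.

The pipeline's universal input is a :class:`SampleTable`: a panel of
microsatellite loci (:class:`LocusDef`) plus one :class:`SampleRecord` per
genotyped individual, carrying the sampling metadata (site, station, season,
sampling period, planar coordinates in metres, body size in cm) alongside the
per-locus allele pairs.

Two on-disk dialects are supported:

* **GenePop** — the classic population-genetics exchange format. It is lossy
  by design (no coordinates, sizes or seasons); population membership is
  carried by POP blocks.
* **annotated CSV** — the lossless format: a header row naming the metadata
  columns followed by two columns per locus (``<locus>_a``, ``<locus>_b``).
  Missing genotypes are empty cells (both alleles of the pair).

Allele values are stored as raw fragment sizes in base pairs; conversion to
repeat units happens only inside distance computations via each locus's
``motif_length``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "LocusDef",
    "LocusGenotype",
    "SampleRecord",
    "SampleTable",
    "GenotypeParseError",
    "SchemaError",
    "read_table",
    "write_table",
    "drop_incomplete",
    "METADATA_COLUMNS",
]

#: Metadata columns of the annotated CSV dialect, in canonical order.
METADATA_COLUMNS = (
    "sample_id",
    "site",
    "station",
    "season",
    "period",
    "x_m",
    "y_m",
    "size_cm",
)

#: Optional column carrying simulation ground truth (genet identity).
GENET_COLUMN = "genet_id"


class GenotypeParseError(ValueError):
    """Malformed genotype data in an input file."""


class SchemaError(ValueError):
    """Structurally inconsistent table (e.g. wrong locus count)."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: name and repeat-motif length in bp.

    ``motif_length`` scales fragment sizes to repeat units ("mutation steps")
    in distance computations. Loci whose alleles are already coded in repeat
    units use the default of 1.
    """

    name: str
    motif_length: int = 1
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")
        if self.ploidy != 2:
            raise ValueError("only diploid (ploidy=2) loci are supported")


@dataclass(frozen=True, order=True)
class LocusGenotype:
    """One diploid single-locus genotype, canonically ordered.

    Both alleles are either present (positive allele sizes, stored with
    ``allele_a <= allele_b``) or both missing (``None``).
    """

    allele_a: int | None
    allele_b: int | None

    def __post_init__(self) -> None:
        a, b = self.allele_a, self.allele_b
        if (a is None) != (b is None):
            raise ValueError(
                "both alleles must be missing or both present, "
                f"got ({a!r}, {b!r})"
            )
        if a is not None and b is not None:
            if a <= 0 or b <= 0:
                raise ValueError(f"allele sizes must be positive, got ({a}, {b})")
            if a > b:  # canonicalize within-locus allele order
                object.__setattr__(self, "allele_a", b)
                object.__setattr__(self, "allele_b", a)

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_heterozygous(self) -> bool:
        return self.allele_a is not None and self.allele_a != self.allele_b

    def alleles(self) -> tuple[int, int]:
        if self.allele_a is None or self.allele_b is None:
            raise ValueError("genotype is missing")
        return (self.allele_a, self.allele_b)


MISSING = LocusGenotype(None, None)


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual with its sampling metadata."""

    sample_id: str
    site: str
    genotype: tuple[LocusGenotype, ...]
    station: str = ""
    season: str = ""
    period: str = ""
    x: float | None = None
    y: float | None = None
    size_cm: float | None = None
    genet_id: str | None = None  # simulation ground truth; None for field data

    def __post_init__(self) -> None:
        if self.size_cm is not None and self.size_cm <= 0:
            raise ValueError(f"size_cm must be positive, got {self.size_cm}")
        object.__setattr__(self, "genotype", tuple(self.genotype))

    @property
    def population_key(self) -> tuple[str, str, str, str]:
        """(site, station, season, period); station is empty for haphazard sampling."""
        return (self.site, self.station, self.season, self.period)

    @property
    def is_complete(self) -> bool:
        return all(not g.is_missing for g in self.genotype)

    @property
    def has_coordinates(self) -> bool:
        return self.x is not None and self.y is not None


@dataclass
class SampleTable:
    """A panel of loci and the records genotyped against it."""

    panel: list[LocusDef]
    records: list[SampleRecord]

    def __post_init__(self) -> None:
        names = [l.name for l in self.panel]
        if len(set(names)) != len(names):
            raise SchemaError("locus names must be unique within a panel")
        n = len(self.panel)
        seen: set[str] = set()
        for rec in self.records:
            if len(rec.genotype) != n:
                raise SchemaError(
                    f"record {rec.sample_id!r} has {len(rec.genotype)} loci, "
                    f"panel has {n}"
                )
            if rec.sample_id in seen:
                raise SchemaError(f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    def population_keys(self) -> list[tuple[str, str, str, str]]:
        """Distinct population keys in first-appearance order."""
        seen: dict[tuple[str, str, str, str], None] = {}
        for rec in self.records:
            seen.setdefault(rec.population_key, None)
        return list(seen)

    def by_population(self) -> dict[tuple[str, str, str, str], "SampleTable"]:
        """Partition the records into one table per population key."""
        groups: dict[tuple[str, str, str, str], list[SampleRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.population_key, []).append(rec)
        return {k: SampleTable(self.panel, v) for k, v in groups.items()}

    def subset(self, predicate) -> "SampleTable":
        return SampleTable(self.panel, [r for r in self.records if predicate(r)])

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to the annotated-CSV column layout."""
        rows = []
        carry_genet = any(r.genet_id is not None for r in self.records)
        for rec in self.records:
            row: dict[str, object] = {
                "sample_id": rec.sample_id,
                "site": rec.site,
                "station": rec.station,
                "season": rec.season,
                "period": rec.period,
                "x_m": rec.x,
                "y_m": rec.y,
                "size_cm": rec.size_cm,
            }
            if carry_genet:
                row[GENET_COLUMN] = rec.genet_id
            for locus, g in zip(self.panel, rec.genotype):
                row[f"{locus.name}_a"] = g.allele_a
                row[f"{locus.name}_b"] = g.allele_b
            rows.append(row)
        columns = list(METADATA_COLUMNS)
        if carry_genet:
            columns.append(GENET_COLUMN)
        for locus in self.panel:
            columns += [f"{locus.name}_a", f"{locus.name}_b"]
        return pd.DataFrame(rows, columns=columns)


def drop_incomplete(table: SampleTable) -> tuple[SampleTable, int]:
    """Keep only records whose multilocus genotype has no missing data.

    Returns the filtered table and the number of records removed. Idempotent.
    """
    kept = [r for r in table.records if r.is_complete]
    return SampleTable(table.panel, kept), len(table.records) - len(kept)


# ---------------------------------------------------------------------------
# annotated CSV
# ---------------------------------------------------------------------------


def _float_or_none(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _read_csv(path: Path, panel: Sequence[LocusDef] | None) -> SampleTable:
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "station": str, "period": str},
        float_precision="round_trip",
    )
    missing_meta = [c for c in ("sample_id", "site") if c not in df.columns]
    if missing_meta:
        raise SchemaError(f"missing metadata columns: {missing_meta}")

    known = set(METADATA_COLUMNS) | {GENET_COLUMN}
    locus_cols = [c for c in df.columns if c not in known]
    names: list[str] = []
    for c in locus_cols:
        if c.endswith("_a"):
            names.append(c[:-2])
        elif not c.endswith("_b"):
            raise SchemaError(f"unrecognized column {c!r}")
    for name in names:
        if f"{name}_b" not in df.columns:
            raise SchemaError(f"locus {name!r} lacks a _b column")

    if panel is not None:
        if [l.name for l in panel] != names:
            raise SchemaError(
                f"supplied panel {[l.name for l in panel]} does not match "
                f"file loci {names}"
            )
        loci = list(panel)
    else:
        loci = [LocusDef(n) for n in names]

    records: list[SampleRecord] = []
    for idx, row in df.iterrows():
        genotype = []
        for name in names:
            a = row[f"{name}_a"]
            b = row[f"{name}_b"]
            a = None if pd.isna(a) else int(a)
            b = None if pd.isna(b) else int(b)
            try:
                genotype.append(LocusGenotype(a, b))
            except ValueError as exc:
                raise GenotypeParseError(
                    f"row {idx + 2} locus {name!r}: {exc}"
                ) from exc
        genet = row.get(GENET_COLUMN)
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                site=str(row["site"]),
                station="" if pd.isna(row.get("station")) else str(row.get("station")),
                season="" if pd.isna(row.get("season")) else str(row.get("season")),
                period="" if pd.isna(row.get("period")) else str(row.get("period")),
                x=_float_or_none(row.get("x_m")),
                y=_float_or_none(row.get("y_m")),
                size_cm=_float_or_none(row.get("size_cm")),
                genotype=tuple(genotype),
                genet_id=None if genet is None or pd.isna(genet) else str(genet),
            )
        )
    return SampleTable(loci, records)


def _write_csv(table: SampleTable, path: Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

_GENEPOP_TITLE = "clonescape genotype export"


def _read_genepop(path: Path, panel: Sequence[LocusDef] | None) -> SampleTable:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError("empty genepop file")
    # line 1 is the title; locus names follow, one per line or comma-separated,
    # until the first POP marker
    names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            names += [n.strip() for n in chunk.split(",") if n.strip()]
        i += 1
    if panel is not None:
        if [l.name for l in panel] != names:
            raise SchemaError("supplied panel does not match file loci")
        loci = list(panel)
    else:
        loci = [LocusDef(n) for n in names]

    records: list[SampleRecord] = []
    pop_index = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_index += 1
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise GenotypeParseError(
                f"line {i}: expected 'id , genotypes', got {line!r}"
            )
        sample_id, geno_part = line.split(",", 1)
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise SchemaError(
                f"line {i}: {len(fields)} genotype fields for {len(loci)} loci"
            )
        genotype = []
        for name, fld in zip(names, fields):
            if len(fld) not in (4, 6) or not fld.isdigit():
                raise GenotypeParseError(
                    f"line {i} locus {name!r}: malformed allele code {fld!r}"
                )
            w = len(fld) // 2
            a, b = int(fld[:w]), int(fld[w:])
            genotype.append(
                LocusGenotype(a or None, b or None)
                if (a == 0) == (b == 0)
                else _raise_half_missing(i, name)
            )
        records.append(
            SampleRecord(
                sample_id=sample_id.strip(),
                site=f"POP{pop_index}",
                genotype=tuple(genotype),
            )
        )
    return SampleTable(loci, records)


def _raise_half_missing(line: int, name: str):
    raise GenotypeParseError(
        f"line {line} locus {name!r}: one allele coded missing (0) but not the other"
    )


def _write_genepop(table: SampleTable, path: Path) -> None:
    out = [_GENEPOP_TITLE]
    out += [l.name for l in table.panel]
    groups: dict[tuple[str, str, str, str], list[SampleRecord]] = {}
    for rec in table.records:
        groups.setdefault(rec.population_key, []).append(rec)
    for key in sorted(groups):
        out.append("POP")
        for rec in groups[key]:
            codes = []
            for g in rec.genotype:
                if g.is_missing:
                    codes.append("000000")
                else:
                    a, b = g.alleles()
                    if a > 999 or b > 999:
                        raise ValueError(
                            f"allele size {max(a, b)} of {rec.sample_id!r} "
                            "exceeds 3-digit genepop coding"
                        )
                    codes.append(f"{a:03d}{b:03d}")
            out.append(f"{rec.sample_id} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

_FORMATS = ("annotated_csv", "genepop")


def read_table(
    path: str | Path,
    format: str = "annotated_csv",
    panel: Sequence[LocusDef] | None = None,
) -> SampleTable:
    """Read a genotype table.

    ``panel`` optionally supplies locus definitions (e.g. motif lengths) that
    neither format carries; its names must match the file's loci.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "annotated_csv":
        return _read_csv(path, panel)
    if format == "genepop":
        return _read_genepop(path, panel)
    raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")


def write_table(table: SampleTable, path: str | Path, format: str = "annotated_csv") -> None:
    """Write a genotype table; the annotated CSV is the lossless dialect."""
    path = Path(path)
    if format == "annotated_csv":
        _write_csv(table, path)
    elif format == "genepop":
        _write_genepop(table, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
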