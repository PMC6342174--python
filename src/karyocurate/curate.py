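"""Table-level curation: raw record CSVs in, integer-only tables out.

Reads chromosome-count record tables in the two CSV dialects common to
count-database exports (a long dialect with an explicit count-type
column, and a wide dialect with separate gametophytic/sporophytic
columns), runs every record through the notation translator, and emits
a long-format curated table with one row per (taxon, count type,
single integer count) plus full provenance: the original record, its
complete translation, flags, and a record index linking rows exploded
from the same source record.  Records the grammar cannot read are kept
as first-class rejects so users can report new notation patterns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .notation import naive_leading_integer, translate_record

__all__ = [
    "GAMETOPHYTIC",
    "SPOROPHYTIC",
    "RawRecord",
    "CuratedRow",
    "CuratedTable",
    "Dialect",
    "LONG_DIALECT",
    "WIDE_DIALECT",
    "read_records",
    "curate_records",
    "filter_table",
    "write_curated_csv",
    "read_curated_csv",
    "write_rejects_csv",
]

GAMETOPHYTIC = "gametophytic"
SPOROPHYTIC = "sporophytic"
_COUNT_TYPES = (GAMETOPHYTIC, SPOROPHYTIC)

# header-cell spellings accepted for the count-type column
_COUNT_TYPE_ALIASES = {
    "gametophytic": GAMETOPHYTIC,
    "n": GAMETOPHYTIC,
    "haploid": GAMETOPHYTIC,
    "sporophytic": SPOROPHYTIC,
    "2n": SPOROPHYTIC,
    "diploid": SPOROPHYTIC,
}


@dataclass(frozen=True)
class RawRecord:
    """One uncurated database row."""

    taxon: str
    count_type: str
    record: str
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.count_type not in _COUNT_TYPES:
            raise ValueError(f"bad count_type {self.count_type!r}")
        if not str(self.record).strip():
            raise ValueError("record string is empty")


@dataclass(frozen=True)
class CuratedRow:
    """One curated observation: a single integer count with provenance."""

    taxon: str
    count_type: str
    count: int
    translation: str  # space-joined counts of the whole source record
    original: str
    flags: frozenset = frozenset()
    record_index: int = 0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("curated counts are positive integers")
        if str(self.count) not in self.translation.split():
            raise ValueError("count must appear in its own translation")


@dataclass
class CuratedTable:
    """A curated long-format table plus the records that failed curation."""

    rows: list[CuratedRow] = field(default_factory=list)
    rejects: list[tuple[RawRecord, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_source_records(self) -> int:
        return len({r.record_index for r in self.rows}) + len(self.rejects)

    def to_frame(self) -> pd.DataFrame:
        """The curated rows as a pandas DataFrame (stable column order)."""
        return pd.DataFrame(
            [
                {
                    "taxon": r.taxon,
                    "count_type": r.count_type,
                    "count": r.count,
                    "translation": r.translation,
                    "original": r.original,
                    "flags": ";".join(sorted(r.flags)),
                    "naive_parse": naive_leading_integer(r.original),
                    "record_index": r.record_index,
                }
                for r in self.rows
            ],
            columns=[
                "taxon",
                "count_type",
                "count",
                "translation",
                "original",
                "flags",
                "naive_parse",
                "record_index",
            ],
        )


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dialect:
    """Maps CSV headers onto the fields the curator needs.

    ``long`` layout: one record per row with taxon, count-type and
    record columns.  ``wide`` layout: one species per row with separate
    gametophytic and sporophytic record columns, melted to long form on
    read.
    """

    layout: str  # "long" | "wide"
    taxon: str = "taxon"
    count_type: str = "count_type"
    record: str = "record"
    gametophytic: str = "gametophytic"
    sporophytic: str = "sporophytic"

    @classmethod
    def from_mapping(cls, cfg: dict) -> "Dialect":
        return cls(**cfg)


LONG_DIALECT = Dialect(layout="long")
WIDE_DIALECT = Dialect(layout="wide", taxon="species")


def _is_blank(value) -> bool:
    return pd.isna(value) or not str(value).strip()


def read_records(
    path: Union[str, Path], dialect: Dialect = LONG_DIALECT
) -> tuple[list[RawRecord], int]:
    """Read raw records from a CSV file.

    Returns ``(records, n_skipped)`` where ``n_skipped`` tallies rows
    whose record cell was empty or missing.  Raises ``ValueError``
    naming the absent header if a mandatory column is missing, and
    propagates pandas parse errors (which carry the offending line) on
    malformed CSV.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])

    if dialect.layout == "long":
        needed = [dialect.taxon, dialect.count_type, dialect.record]
    elif dialect.layout == "wide":
        needed = [dialect.taxon, dialect.gametophytic, dialect.sporophytic]
    else:
        raise ValueError(f"unknown dialect layout {dialect.layout!r}")
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")

    records: list[RawRecord] = []
    skipped = 0
    if dialect.layout == "long":
        for i, row in df.iterrows():
            if _is_blank(row[dialect.record]):
                skipped += 1
                continue
            ct_raw = str(row[dialect.count_type]).strip().lower()
            if ct_raw not in _COUNT_TYPE_ALIASES:
                raise ValueError(
                    f"unrecognized count type {row[dialect.count_type]!r} "
                    f"on data row {i + 1}"
                )
            records.append(
                RawRecord(
                    taxon=str(row[dialect.taxon]).strip(),
                    count_type=_COUNT_TYPE_ALIASES[ct_raw],
                    record=str(row[dialect.record]),
                    source_id=f"{path}:{i + 1}",
                )
            )
    else:
        for i, row in df.iterrows():
            any_cell = False
            for col, ctype in (
                (dialect.gametophytic, GAMETOPHYTIC),
                (dialect.sporophytic, SPOROPHYTIC),
            ):
                if _is_blank(row[col]):
                    continue
                any_cell = True
                records.append(
                    RawRecord(
                        taxon=str(row[dialect.taxon]).strip(),
                        count_type=ctype,
                        record=str(row[col]),
                        source_id=f"{path}:{i + 1}:{ctype}",
                    )
                )
            if not any_cell:
                skipped += 1
    return records, skipped


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------


def curate_records(records: Iterable[RawRecord]) -> CuratedTable:
    """Translate raw records and explode them into single-count rows.

    Each parsed record becomes one row per translated count (a record
    translating to "38 38" yields two rows sharing a record index).
    Unparsed records land in ``rejects`` with their notes.  Zero counts
    — legal in the notation but meaningless as observations — are
    dropped from rows with a reject entry if the whole record was zero.
    """
    table = CuratedTable()
    for idx, rec in enumerate(records):
        tr = translate_record(rec.record)
        if not tr.parsed:
            table.rejects.append((rec, "; ".join(tr.notes)))
            continue
        positive = [c for c in tr.counts if c > 0]
        if not positive:
            table.rejects.append(
                (rec, "translation contains no positive count")
            )
            continue
        for count in positive:
            table.rows.append(
                CuratedRow(
                    taxon=rec.taxon,
                    count_type=rec.count_type,
                    count=count,
                    translation=tr.counts_string(),
                    original=rec.record,
                    flags=frozenset(tr.flags),
                    record_index=idx,
                )
            )
    return table


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _genus_of(taxon: str) -> str:
    return taxon.split()[0].casefold() if taxon.split() else ""


def filter_table(
    table: CuratedTable,
    genus: Optional[str] = None,
    species: Optional[Sequence[str]] = None,
    count_type: str = "combined",
) -> CuratedTable:
    """Restrict a curated table to a genus or species list and count type.

    Genus matching compares the first whitespace-delimited token of the
    binomial, case-insensitively; species matching is exact.  The
    ``"combined"`` count type keeps gametophytic and sporophytic rows
    as they are, without rescaling.  Rejects are carried through for
    reporting.
    """
    if genus is None and species is None:
        raise ValueError("provide a genus or a species list")
    if species is not None and len(species) == 0:
        raise ValueError("species selection is empty")
    if count_type not in (*_COUNT_TYPES, "combined"):
        raise ValueError(f"bad count_type {count_type!r}")

    wanted_species = (
        {s.casefold() for s in species} if species is not None else None
    )
    genus_cf = genus.casefold() if genus is not None else None

    def keep(taxon: str, ctype: str) -> bool:
        if count_type != "combined" and ctype != count_type:
            return False
        if wanted_species is not None and taxon.casefold() in wanted_species:
            return True
        if genus_cf is not None and _genus_of(taxon) == genus_cf:
            return True
        return False

    rows = [r for r in table.rows if keep(r.taxon, r.count_type)]
    return CuratedTable(rows=rows, rejects=list(table.rejects))


def double_gametophytic(table: CuratedTable) -> CuratedTable:
    """Rescale gametophytic rows to the sporophytic 2n scale (2 x n).

    Off by default everywhere; provided for users who want a common
    scale in combined views.  Rescaled rows are flagged
    ``haploid_doubled`` and relabeled sporophytic.
    """
    rows = []
    for r in table.rows:
        if r.count_type == GAMETOPHYTIC:
            doubled = r.count * 2
            rows.append(
                CuratedRow(
                    taxon=r.taxon,
                    count_type=SPOROPHYTIC,
                    count=doubled,
                    translation=str(doubled),
                    original=r.original,
                    flags=r.flags | {"haploid_doubled"},
                    record_index=r.record_index,
                )
            )
        else:
            rows.append(r)
    return CuratedTable(rows=rows, rejects=list(table.rejects))


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------


def write_curated_csv(table: CuratedTable, path: Union[str, Path]) -> None:
    """Write the curated table as UTF-8 CSV with a stable column order."""
    table.to_frame().to_csv(path, index=False, encoding="utf-8")


def read_curated_csv(path: Union[str, Path]) -> CuratedTable:
    """Read back a CSV written by :func:`write_curated_csv`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows = [
        CuratedRow(
            taxon=row["taxon"],
            count_type=row["count_type"],
            count=int(row["count"]),
            translation=row["translation"],
            original=row["original"],
            flags=frozenset(f for f in row["flags"].split(";") if f),
            record_index=int(row["record_index"]),
        )
        for _, row in df.iterrows()
    ]
    return CuratedTable(rows=rows)


def write_rejects_csv(table: CuratedTable, path: Union[str, Path]) -> None:
    """Write rejected records ({taxon, count_type, original, reason})."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon", "count_type", "original", "reason"])
        for rec, reason in table.rejects:
            writer.writerow([rec.taxon, rec.count_type, rec.record, reason])
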