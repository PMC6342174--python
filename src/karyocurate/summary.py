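"""Quantitative summaries of curated chromosome-count tables.

Per-species record frequencies at each count, percentage matrices for
heatmap display, modal counts, intraspecific count variation, and
ploidy-level inference against a base chromosome number x.  Ploidy
works on the sporophytic (2n) scale: a gametophytic (n) count is
doubled first, then the ploidy level p is the nearest positive integer
to 2n / x, with the aneuploidy residual 2n - p*x reported rather than
snapped to zero.  The base number is a user input (it comes from the
literature for the lineage in question); a gcd-based helper can
suggest candidates but is explicitly a heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .curate import GAMETOPHYTIC, SPOROPHYTIC, CuratedTable

__all__ = [
    "FrequencyTable",
    "PloidyAssignment",
    "count_frequencies",
    "heatmap_percentages",
    "species_mode",
    "infer_ploidy",
    "ploidy_table",
    "detect_intraspecific_variation",
    "suggest_base_number",
]


@dataclass
class FrequencyTable:
    """Record frequencies per (species, count) pair.

    ``entries`` maps ``(species, count)`` to the number of curated
    records with that count.  Species are ordered lexicographically and
    counts ascending wherever the table is rendered.
    """

    entries: dict[tuple[str, int], int]

    @property
    def species(self) -> list[str]:
        return sorted({s for s, _ in self.entries})

    @property
    def counts(self) -> list[int]:
        return sorted({c for _, c in self.entries})

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame {species, count, n_records}."""
        rows = [
            {"species": s, "count": c, "n_records": n}
            for (s, c), n in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["species", "count", "n_records"])


@dataclass(frozen=True)
class PloidyAssignment:
    """Ploidy call for one count against a base number x.

    ``count`` is on the sporophytic 2n scale; ``residual`` is
    ``count - p * x`` (zero iff the count is euploid, an exact multiple
    of x).
    """

    count: int
    base_number_x: int
    ploidy_p: int
    residual: int

    @property
    def euploid(self) -> bool:
        return self.residual == 0


def count_frequencies(table: CuratedTable) -> FrequencyTable:
    """Exact multiset tally of (species, count) pairs in a curated table."""
    entries: dict[tuple[str, int], int] = {}
    for row in table.rows:
        key = (row.taxon, row.count)
        entries[key] = entries.get(key, 0) + 1
    return FrequencyTable(entries)


def heatmap_percentages(
    freq: FrequencyTable, normalize: str = "species"
) -> pd.DataFrame:
    """Percentage matrix (species x count) for heatmap display.

    With ``normalize="species"`` (default) each cell is 100 times the
    record frequency divided by that species' total, so every row sums
    to 100 and species with few records remain comparable.  With
    ``normalize="global"`` the denominator is the grand total instead.
    Absent (species, count) cells are 0.
    """
    if not freq.entries:
        raise ValueError("frequency table is empty")
    if normalize not in ("species", "global"):
        raise ValueError(f"bad normalize mode {normalize!r}")

    mat = pd.DataFrame(
        0.0, index=freq.species, columns=freq.counts, dtype=float
    )
    for (s, c), n in freq.entries.items():
        mat.loc[s, c] = n
    if normalize == "species":
        mat = mat.div(mat.sum(axis=1), axis=0) * 100.0
    else:
        mat = mat / freq.total * 100.0
    return mat


def species_mode(freq: FrequencyTable, species: str) -> list[int]:
    """All modal counts for one species, ascending (ties kept, not broken)."""
    tallies = {
        c: n for (s, c), n in freq.entries.items() if s == species
    }
    if not tallies:
        raise KeyError(f"species {species!r} not in frequency table")
    best = max(tallies.values())
    return sorted(c for c, n in tallies.items() if n == best)


def infer_ploidy(
    count: int, count_type: str, base_number_x: int
) -> PloidyAssignment:
    """Infer the ploidy level of one count given a base number x.

    Gametophytic counts are doubled onto the 2n scale first.  The
    ploidy level is the nearest positive integer to 2n / x (exact .5
    rounds up), and the residual keeps whatever aneuploid offset
    remains.  E.g. a sporophytic count of 124 with x = 31 is a
    tetraploid (4 * 31 = 124, residual 0).
    """
    if base_number_x < 1:
        raise ValueError("base number x must be a positive integer")
    if count < 1:
        raise ValueError("count must be a positive integer")
    if count_type not in (GAMETOPHYTIC, SPOROPHYTIC):
        raise ValueError(f"bad count_type {count_type!r}")

    scaled = count * 2 if count_type == GAMETOPHYTIC else count
    # round half up, clamp to >= 1
    p = max(1, math.floor(scaled / base_number_x + 0.5))
    return PloidyAssignment(
        count=scaled,
        base_number_x=base_number_x,
        ploidy_p=p,
        residual=scaled - p * base_number_x,
    )


def ploidy_table(table: CuratedTable, base_number_x: int) -> pd.DataFrame:
    """Ploidy assignment for every row of a curated table.

    Columns: {species, count, count_type, x, p, residual, euploid};
    ``count`` is the original (undoubled) curated count.
    """
    rows = []
    for r in table.rows:
        pa = infer_ploidy(r.count, r.count_type, base_number_x)
        rows.append(
            {
                "species": r.taxon,
                "count": r.count,
                "count_type": r.count_type,
                "x": base_number_x,
                "p": pa.ploidy_p,
                "residual": pa.residual,
                "euploid": pa.euploid,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "count", "count_type", "x", "p", "residual", "euploid"],
    )


def detect_intraspecific_variation(
    freq: FrequencyTable,
) -> list[tuple[str, list[int]]]:
    """Species recorded at two or more distinct counts.

    Multiple counts within a species often signal a polyploid series or
    unrecognized autopolyploidy; each such species is returned with its
    ascending distinct count list.
    """
    per_species: dict[str, set[int]] = {}
    for (s, c), _n in freq.entries.items():
        per_species.setdefault(s, set()).add(c)
    return [
        (s, sorted(cs))
        for s, cs in sorted(per_species.items())
        if len(cs) >= 2
    ]


def suggest_base_number(counts: Iterable[int]) -> Optional[int]:
    """Heuristic candidate base number: gcd of the counts, halved while even.

    Purely a convenience for exploration — the base number of a lineage
    should come from the literature, not from this helper.  Returns
    ``None`` for an empty input.
    """
    counts = [int(c) for c in counts if c > 0]
    if not counts:
        return None
    g = math.gcd(*counts) if len(counts) > 1 else counts[0]
    # a sporophytic euploid series shares at least a factor of 2x
    return g // 2 if g % 2 == 0 and g > 1 else g
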