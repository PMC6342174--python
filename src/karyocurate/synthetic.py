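"""Synthetic count tables with known ground truth.

Generates genera of species whose chromosome counts follow euploid
polyploid series (2x, 4x, ... against a per-genus base number x, with
an optional aneuploid fraction), then "messifies" each true record
into a raw notation string drawn from the pattern families the parser
documents: plain integers, bivalent/univalent splits, B-chromosome
additions, comma lists with parenthetical metadata, semicolon
alternatives, fragment suffixes, standalone two-count ranges, and
"etc" filler.  Generator and grammar share intent by construction:
every family emitted here must round-trip through the translator back
to the true counts, which is the module's core tested property.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .curate import GAMETOPHYTIC, SPOROPHYTIC, RawRecord

__all__ = [
    "TrueRecord",
    "GroundTruth",
    "generate_ground_truth",
    "messify",
    "DEFAULT_STYLE_WEIGHTS",
    "write_raw_csv",
    "write_truth_csv",
]


@dataclass(frozen=True)
class TrueRecord:
    """One ground-truth observation before corruption into notation."""

    taxon: str
    count_type: str
    counts: tuple[int, ...]  # true integer counts, 2n scale for sporophytic


@dataclass
class GroundTruth:
    """A generated table of true counts plus the parameters behind it."""

    records: list[TrueRecord]
    base_numbers: dict[str, int]  # genus -> x
    seed: int

    def multiset(self) -> dict[tuple[str, str, int], int]:
        """Multiset of (taxon, count_type, count) over all records."""
        out: dict[tuple[str, str, int], int] = {}
        for rec in self.records:
            for c in rec.counts:
                key = (rec.taxon, rec.count_type, c)
                out[key] = out.get(key, 0) + 1
        return out


_GENUS_STEMS = [
    "Anemia", "Blechnum", "Gentiana", "Gomphrena", "Barnardia",
    "Heracleum", "Chrysanthemum", "Solanum", "Carex", "Silene",
    "Festuca", "Viola", "Salix", "Rosa", "Allium",
]
_EPITHETS = [
    "adiantifolia", "occidentale", "terglouensis", "globosa", "japonica",
    "sphondylium", "morifolium", "alpina", "vulgaris", "montana",
    "elegans", "minor", "major", "gracilis", "robusta",
]


def generate_ground_truth(
    n_genera: int = 4,
    species_per_genus: int = 5,
    x_range: tuple[int, int] = (7, 40),
    max_ploidy: int = 8,
    aneuploid_fraction: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Generate a reproducible ground-truth count table.

    Each genus draws a base number x from ``x_range``; each species
    keeps 1-3 even ploidy levels from {2, 4, ..., max_ploidy} and gets
    1-5 records spread across them.  Sporophytic records carry 2n =
    p * x; gametophytic records carry n = p * x / 2.  A fraction
    ``aneuploid_fraction`` of records is shifted off the euploid value
    by 1-2 chromosomes on the 2n scale (even shifts for gametophytic
    records so n stays an integer).  The seed fixes everything.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("n_genera and species_per_genus must be positive")
    if max_ploidy < 2 or max_ploidy % 2:
        raise ValueError("max_ploidy must be an even integer >= 2")
    if not (1 <= x_range[0] <= x_range[1]):
        raise ValueError("x_range must be a positive non-empty interval")
    if not 0.0 <= aneuploid_fraction <= 1.0:
        raise ValueError("aneuploid_fraction must be in [0, 1]")

    rng = random.Random(seed)
    levels_pool = list(range(2, max_ploidy + 1, 2))
    records: list[TrueRecord] = []
    base_numbers: dict[str, int] = {}

    for gi in range(n_genera):
        genus = (
            _GENUS_STEMS[gi]
            if gi < len(_GENUS_STEMS)
            else f"Genus{gi + 1}"
        )
        x = rng.randint(*x_range)
        base_numbers[genus] = x
        for si in range(species_per_genus):
            epithet = (
                _EPITHETS[si] if si < len(_EPITHETS) else f"species{si + 1}"
            )
            taxon = f"{genus} {epithet}"
            k_levels = rng.randint(1, min(3, len(levels_pool)))
            levels = sorted(rng.sample(levels_pool, k_levels))
            n_records = rng.randint(1, 5)
            for _ in range(n_records):
                count_type = rng.choice((GAMETOPHYTIC, SPOROPHYTIC))
                # usually one count per record; sometimes a pair, which
                # exercises the multi-count pattern families
                n_counts = 2 if len(levels) >= 2 and rng.random() < 0.25 else 1
                chosen = rng.sample(levels, n_counts)
                counts = []
                for p in sorted(chosen):
                    two_n = p * x
                    if rng.random() < aneuploid_fraction:
                        shift = rng.choice(
                            (-2, 2)
                            if count_type == GAMETOPHYTIC
                            else (-2, -1, 1, 2)
                        )
                        two_n = max(2, two_n + shift)
                    counts.append(
                        two_n // 2 if count_type == GAMETOPHYTIC else two_n
                    )
                # distinct ascending counts keep range rendering valid
                counts = sorted(set(counts))
                records.append(TrueRecord(taxon, count_type, tuple(counts)))
    return GroundTruth(records=records, base_numbers=base_numbers, seed=seed)


# ---------------------------------------------------------------------------
# messification: true counts -> raw notation strings
# ---------------------------------------------------------------------------


def _bivalent_split(count: int, rng: random.Random) -> str:
    """Render a count as a bivalent+univalent configuration summing to it."""
    if count < 2:
        return str(count)
    lo, hi = (count + 3) // 4, count // 2
    k = rng.randint(lo, hi)
    r = count - 2 * k
    return f"{k}II+{r}I" if r else f"{k}II"


def _render_plain(counts, rng):
    return ", ".join(str(c) for c in counts)


def _render_bivalent(counts, rng):
    return ";".join(_bivalent_split(c, rng) for c in counts)


def _render_b_chromosome(counts, rng):
    parts = []
    for c in counts:
        m = rng.randint(1, 3)
        suffix = rng.choice((f"{m}B", f"{m}Bs", f"{m}BI" if m == 1 else f"{m}B"))
        base = (
            _bivalent_split(c, rng) if rng.random() < 0.5 else str(c)
        )
        parts.append(f"{base}+{suffix}")
    return ", ".join(parts)


def _render_parenthetical(counts, rng):
    parts = [str(c) for c in counts]
    meta = ", ".join(str(rng.randint(1, 4)) for _ in range(rng.randint(1, 4)))
    parts[rng.randrange(len(parts))] += f"({meta})"
    return ", ".join(parts)


def _render_fragment(counts, rng):
    parts = [str(c) for c in counts]
    parts[-1] += "f"
    return ", ".join(parts)


def _render_range(counts, rng):
    if len(counts) != 2 or counts[0] >= counts[1]:
        return None
    dash = rng.choice("-‐–")
    return f"{counts[0]}{dash}{counts[1]}"


def _render_supernumerary(counts, rng):
    parts = []
    for c in counts:
        hi = rng.randint(1, 13)
        parts.append(f"{c}+0-{hi}")
    return ", ".join(parts)


def _render_etc(counts, rng):
    return ", ".join(str(c) for c in counts) + ", etc"


#: pattern families the messifier can emit.  Each renderer returns a raw
#: string whose translation recovers the record's true counts exactly,
#: or None when the family cannot represent the record.
_FAMILIES = {
    "plain": _render_plain,
    "bivalent": _render_bivalent,
    "b_chromosome": _render_b_chromosome,
    "parenthetical": _render_parenthetical,
    "fragment": _render_fragment,
    "range": _render_range,
    "supernumerary": _render_supernumerary,
    "etc": _render_etc,
}

DEFAULT_STYLE_WEIGHTS = {
    "plain": 0.30,
    "bivalent": 0.20,
    "b_chromosome": 0.12,
    "parenthetical": 0.08,
    "fragment": 0.08,
    "range": 0.07,
    "supernumerary": 0.07,
    "etc": 0.08,
}


def messify(
    truth: GroundTruth,
    style_weights: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> list[RawRecord]:
    """Render every true record as a raw notation string.

    One pattern family is sampled per record according to
    ``style_weights`` (which must sum to 1 over known families); a
    family that cannot represent the record (e.g. the range family for
    a single-count record) is resampled, falling back to the plain
    rendering if no weighted family can represent it.
    """
    weights = dict(style_weights or DEFAULT_STYLE_WEIGHTS)
    unknown = set(weights) - set(_FAMILIES)
    if unknown:
        raise ValueError(f"unknown pattern families: {sorted(unknown)}")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("style weights must sum to 1")

    rng = random.Random(seed)
    names = sorted(weights)
    probs = [weights[n] for n in names]
    out: list[RawRecord] = []
    for rec in truth.records:
        rendered = None
        untried = set(names)
        while rendered is None and untried:
            family = rng.choices(names, weights=probs, k=1)[0]
            untried.discard(family)
            rendered = _FAMILIES[family](list(rec.counts), rng)
        if rendered is None:
            rendered = _render_plain(list(rec.counts), rng)
        out.append(
            RawRecord(
                taxon=rec.taxon,
                count_type=rec.count_type,
                record=rendered,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV output (same dialects the curation layer reads)
# ---------------------------------------------------------------------------


def write_raw_csv(records: list[RawRecord], path: Union[str, Path]) -> None:
    """Write raw records in the long CSV dialect {taxon, count_type, record}."""
    pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "count_type": r.count_type,
                "record": r.record,
            }
            for r in records
        ],
        columns=["taxon", "count_type", "record"],
    ).to_csv(path, index=False, encoding="utf-8")


def write_truth_csv(truth: GroundTruth, path: Union[str, Path]) -> None:
    """Write the ground truth, one row per (taxon, count_type, count)."""
    rows = []
    for rec in truth.records:
        for c in rec.counts:
            rows.append(
                {
                    "taxon": rec.taxon,
                    "count_type": rec.count_type,
                    "count": c,
                }
            )
    pd.DataFrame(rows, columns=["taxon", "count_type", "count"]).to_csv(
        path, index=False, encoding="utf-8"
    )
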