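"""Parsing of cytological chromosome-count notation.

Raw chromosome-count records, as exported from public count databases,
mix plain integers with meiotic-configuration notation.  A record such
as ``"40II+44I"`` means 40 bivalents (each a pair of homologous
chromosomes, hence 80 chromosomes) plus 44 univalents, for an actual
complement of 124 chromosomes.  Records may also carry B chromosomes
(``"+1B"``, supernumerary and excluded from the complement total),
supernumerary ranges (``"34+0-13"``), alternative observations joined
by ``";"`` or ``","``, approximate markers (``"c."``), fragment
suffixes (``"30f"``), parenthetical record-multiplicity metadata, and
standalone count ranges (``"40-44"``).

This module turns one raw record string into the ordered list of
integer chromosome counts it encodes.  The pipeline is::

    raw string --normalize--> canonical string
               --split------> alternative expressions
               --parse------> additive terms (multiplicity x valence)
               --evaluate---> integer counts

Parsing never raises out of :func:`translate_record`: records the
grammar does not recognize come back with ``status="unparsed"`` and
human-readable notes, so curation stays total over a whole table.  The
term grammar is table-driven (:data:`TERM_PATTERNS`) so new pattern
families can be registered without touching the parser core.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

__all__ = [
    "TermKind",
    "Term",
    "ParsedExpression",
    "Translation",
    "UnparseableExpression",
    "normalize_record",
    "split_alternatives",
    "parse_expression",
    "evaluate_expression",
    "translate_record",
    "naive_leading_integer",
    "roman_to_int",
    "TERM_PATTERNS",
]

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class TermKind(str, Enum):
    """What an additive term contributes to the chromosome total."""

    CHROMOSOMAL = "chromosomal"
    B_CHROMOSOME = "b_chromosome"
    SUPERNUMERARY_RANGE = "supernumerary_range"


@dataclass(frozen=True)
class Term:
    """One additive term of a count expression.

    A chromosomal term contributes ``multiplicity * valence``
    chromosomes (``40II`` -> 40 x 2 = 80; a plain integer is stored
    with valence 1 so it contributes its own value).  B-chromosome and
    supernumerary-range terms contribute zero.
    """

    multiplicity: int
    valence: int = 1
    kind: TermKind = TermKind.CHROMOSOMAL
    range_hi: Optional[int] = None

    def __post_init__(self) -> None:
        if self.multiplicity < 0:
            raise ValueError("multiplicity must be non-negative")
        if self.valence < 1:
            raise ValueError("valence must be a positive integer")
        if self.kind is TermKind.SUPERNUMERARY_RANGE and self.range_hi is None:
            raise ValueError("supernumerary_range terms need range_hi")

    @property
    def chromosomes(self) -> int:
        """Chromosomes this term adds to the complement total."""
        if self.kind is TermKind.CHROMOSOMAL:
            return self.multiplicity * self.valence
        return 0


@dataclass
class ParsedExpression:
    """The structured form of a single count expression."""

    terms: list[Term]
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not any(t.kind is TermKind.CHROMOSOMAL for t in self.terms):
            raise UnparseableExpression(
                "expression has no chromosomal term", token=""
            )


@dataclass
class Translation:
    """Integer counts extracted from one raw record, with diagnostics.

    ``original`` preserves the source string byte-for-byte so curated
    output can always be displayed next to what the database reported.
    """

    original: str
    counts: list[int]
    flags: set[str] = field(default_factory=set)
    status: str = "parsed"  # "parsed" | "unparsed"
    notes: list[str] = field(default_factory=list)

    @property
    def parsed(self) -> bool:
        return self.status == "parsed"

    def counts_string(self) -> str:
        """Space-joined counts, the display form of a translation."""
        return " ".join(str(c) for c in self.counts)


class UnparseableExpression(ValueError):
    """Raised when an expression contains a token outside the grammar."""

    def __init__(self, message: str, token: str) -> None:
        super().__init__(message)
        self.token = token


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

# unicode dash variants seen in database exports: hyphen, non-breaking
# hyphen, figure dash, en dash, em dash, horizontal bar, minus sign
_DASHES = "‐‑‒–—―−"
_DASH_TABLE = str.maketrans({d: "-" for d in _DASHES})

# letter run directly after a digit run is a marker (valence, B, S, F)
_MARKER_RE = re.compile(r"(\d)([a-zA-Z]+)")


def normalize_record(raw: str) -> str:
    """Canonicalize a raw record string before any pattern matching.

    Maps every unicode dash variant to ASCII ``"-"``, collapses runs of
    whitespace to single spaces, trims the ends, and upper-cases marker
    letters (valence roman numerals, B/S/F suffixes) that directly
    follow a digit.  Everything else is left unchanged.
    """
    if not raw or not raw.strip():
        raise ValueError("record string is empty")
    s = raw.translate(_DASH_TABLE)
    s = re.sub(r"\s+", " ", s).strip()
    s = _MARKER_RE.sub(lambda m: m.group(1) + m.group(2).upper(), s)
    return s


# ---------------------------------------------------------------------------
# splitting into alternative expressions
# ---------------------------------------------------------------------------

_PAREN_GROUP_RE = re.compile(r"\s*\([^()]*\)")
_ETC_RE = re.compile(r"^etc\.?$", re.IGNORECASE)


def split_alternatives(canonical: str) -> list[str]:
    """Split a canonical record into its alternative count expressions.

    Records often list several independent observations separated by
    ``";"`` or ``","``.  Parenthetical groups after a count are
    record-multiplicity metadata and are deleted before splitting;
    literal ``etc`` tokens are dropped.  Order is preserved and empty
    fragments removed.

    Raises :class:`UnparseableExpression` on unbalanced parentheses.
    """
    depth = 0
    for ch in canonical:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise UnparseableExpression("unbalanced parentheses", token=")")
    if depth != 0:
        raise UnparseableExpression("unbalanced parentheses", token="(")

    stripped = _PAREN_GROUP_RE.sub("", canonical)
    parts = re.split(r"[;,]", stripped)
    out = []
    for part in parts:
        part = part.strip()
        if not part or _ETC_RE.match(part):
            continue
        out.append(part)
    return out


# ---------------------------------------------------------------------------
# term grammar (table-driven)
# ---------------------------------------------------------------------------

_ROMAN_VALUES = {"I": 1, "V": 5, "X": 10}


def roman_to_int(roman: str) -> int:
    """Value of a roman numeral valence marker (I..VIII and beyond)."""
    total = 0
    prev = 0
    for ch in reversed(roman.upper()):
        v = _ROMAN_VALUES[ch]
        total = total - v if v < prev else total + v
        prev = max(prev, v)
    return total


_ROMAN_RE = r"(?:VIII|VII|VI|V|IV|III|II|I)"


def _plain_integer(m: re.Match) -> tuple[Term, set[str]]:
    # an already-summed count: contributes its own value
    return Term(int(m.group(1)), 1, TermKind.CHROMOSOMAL), set()


def _valence_term(m: re.Match) -> tuple[Term, set[str]]:
    return (
        Term(int(m.group(1)), roman_to_int(m.group(2)), TermKind.CHROMOSOMAL),
        set(),
    )


def _b_chromosome(m: re.Match) -> tuple[Term, set[str]]:
    return (
        Term(int(m.group(1)), 1, TermKind.B_CHROMOSOME),
        {"has_b_chromosomes"},
    )


def _fragment(m: re.Match) -> tuple[Term, set[str]]:
    # the biological meaning of the "f" suffix is not standardized;
    # keep the number and flag the record
    return Term(int(m.group(1)), 1, TermKind.CHROMOSOMAL), {"fragment"}


def _supernumerary_range(m: re.Match) -> tuple[Term, set[str]]:
    lo, hi = int(m.group(1)), int(m.group(2))
    return (
        Term(lo, 1, TermKind.SUPERNUMERARY_RANGE, range_hi=hi),
        {"has_supernumerary_range"},
    )


#: the term grammar: (name, compiled pattern, handler, leading_ok).
#: Handlers return (Term, flags).  Patterns are tried in order against a
#: whole term; extend this list to register new pattern families.
TERM_PATTERNS: list[tuple[str, re.Pattern, Callable, bool]] = [
    ("valence", re.compile(rf"^(\d+)({_ROMAN_RE})$"), _valence_term, True),
    (
        "b_chromosome",
        re.compile(rf"^(\d+)B(?:S|{_ROMAN_RE})?$"),
        _b_chromosome,
        True,
    ),
    ("fragment", re.compile(r"^(\d+)F$"), _fragment, True),
    ("plain_integer", re.compile(r"^(\d+)$"), _plain_integer, True),
    # a range term is only legal as a non-leading addition (a
    # supernumerary series); a leading range is a standalone range
    # record and is expanded upstream by translate_record
    (
        "supernumerary_range",
        re.compile(r"^(\d+)-(\d+)$"),
        _supernumerary_range,
        False,
    ),
]

_APPROX_RE = re.compile(r"^C(?:A)?\.\s*", re.IGNORECASE)
_STANDALONE_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")


def _strip_approx(expr: str) -> tuple[str, set[str]]:
    m = _APPROX_RE.match(expr)
    if m:
        return expr[m.end():], {"approximate"}
    return expr, set()


def parse_expression(expr: str) -> ParsedExpression:
    """Parse a single alternative expression into additive terms.

    The expression is split on ``"+"``; every term must match exactly
    one entry of :data:`TERM_PATTERNS`.  A leading ``c.``/``ca.``
    approximate marker is stripped and flagged.

    Raises :class:`UnparseableExpression` for any token outside the
    grammar, carrying the offending token.
    """
    expr = expr.strip()
    expr, flags = _strip_approx(expr)
    if not expr:
        raise UnparseableExpression("empty expression", token=expr)

    terms: list[Term] = []
    for i, token in enumerate(t.strip() for t in expr.split("+")):
        if not token:
            raise UnparseableExpression("empty additive term", token="+")
        for _name, pattern, handler, leading_ok in TERM_PATTERNS:
            m = pattern.match(token)
            if m and (leading_ok or i > 0):
                term, term_flags = handler(m)
                terms.append(term)
                flags |= term_flags
                break
        else:
            raise UnparseableExpression(
                f"unrecognized token {token!r}", token=token
            )
    return ParsedExpression(terms=terms, flags=flags)


def evaluate_expression(parsed: ParsedExpression) -> int:
    """Total chromosome count of a parsed expression.

    Sums ``multiplicity * valence`` over chromosomal terms; B
    chromosomes and supernumerary ranges contribute zero (they are
    dispensable additions outside the standard complement).
    """
    return sum(t.chromosomes for t in parsed.terms)


# ---------------------------------------------------------------------------
# record-level translation
# ---------------------------------------------------------------------------


def translate_record(raw: str) -> Translation:
    """Translate one raw record string into its integer counts.

    Normalizes, splits into alternatives, and evaluates each: a
    standalone range ``"a-b"`` yields its two endpoint counts; any
    other alternative is parsed and summed.  Counts keep input order
    and duplicates (two identical alternatives mean two records).

    Never raises: a record the grammar cannot handle comes back with
    ``status="unparsed"`` and explanatory notes.
    """
    if raw is None or not str(raw).strip():
        return Translation(
            original="" if raw is None else str(raw),
            counts=[],
            status="unparsed",
            notes=["empty record"],
        )
    raw = str(raw)
    canonical = normalize_record(raw)
    counts: list[int] = []
    flags: set[str] = set()
    notes: list[str] = []

    try:
        alternatives = split_alternatives(canonical)
    except UnparseableExpression as exc:
        return Translation(
            original=raw, counts=[], status="unparsed", notes=[str(exc)]
        )

    if not alternatives:
        notes.append("no count expression after dropping filler tokens")

    for alt in alternatives:
        body, approx = _strip_approx(alt)
        m = _STANDALONE_RANGE_RE.match(body)
        if m:
            # a whole-expression range reports the two endpoint counts,
            # not every intermediate integer
            counts.extend([int(m.group(1)), int(m.group(2))])
            flags |= approx
            continue
        try:
            parsed = parse_expression(alt)
        except UnparseableExpression as exc:
            notes.append(f"dropped alternative {alt!r}: {exc}")
            continue
        counts.append(evaluate_expression(parsed))
        flags |= parsed.flags

    if counts and all(c == 0 for c in counts):
        # a record that translates only to zero is almost certainly a
        # notation artifact; keep it but mark it
        flags.add("suspicious_zero")

    if counts:
        return Translation(raw, counts, flags, "parsed", notes)
    if not notes:
        notes.append("no counts produced")
    return Translation(raw, [], flags, "unparsed", notes)


def naive_leading_integer(raw: str) -> Optional[int]:
    """The lossy leading-integer reading of a record.

    Returns the first maximal digit run of the normalized string, or
    ``None`` if the record contains no digits.  This reproduces the
    behavior of CSV exports that reduce ``"40II+44I"`` to ``40``,
    discarding the rest of the complement — kept as a baseline column
    so curated output can be compared side by side with it.
    """
    if raw is None or not str(raw).strip():
        return None
    canonical = normalize_record(str(raw))
    m = re.search(r"\d+", canonical)
    return int(m.group(0)) if m else None
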