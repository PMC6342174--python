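# Methods

## Notation model

A raw chromosome-count record is treated as a list of *alternative
expressions* (independent observations) separated by `;` or top-level
`,`. Each expression is a `+`-joined sum of terms:

- **plain integer** — an already-summed count; contributes its own
  value;
- **meiotic configuration** `mR` with `R` a roman numeral (I = 
  univalent, II = bivalent, III = trivalent, …) — contributes
  `m × valence` chromosomes; numerals up to VIII are accepted because
  higher multivalents occur in real karyotypes and the arithmetic
  generalizes trivially;
- **B chromosomes** `mB` / `mBs` / `mBI` — supernumerary, dispensable,
  contribute zero to the complement total; flagged;
- **supernumerary range** `a-b` as a non-leading additive term —
  contributes zero; flagged;
- **fragment suffix** `f` on a number — the letter is stripped, the
  number kept, and the record flagged (the cytological meaning of the
  suffix is not standardized, so we only flag it);
- **approximate prefix** `c.` / `ca.` — stripped and flagged.

Three whole-expression conventions are forced by how curated
translations are conventionally printed:

- a *standalone* range `a-b` expands to its two endpoints only, never
  the intermediate integers (`40-44` → 40, 44);
- parenthetical groups after a count are record-multiplicity metadata
  and are deleted, not expanded into repeated rows (`64(1, 1, 1, 4,
  1, 1)` → a single 64);
- literal `etc` / `etc.` tokens are dropped with a note.

Normalization precedes all matching: every unicode dash variant
(hyphen, non-breaking hyphen, en/em dash, minus sign…) maps to ASCII
`-`, whitespace collapses to single spaces, and marker letters
following digits are upper-cased; remaining matching is
case-insensitive. The term grammar is a table
(`notation.TERM_PATTERNS`) so new pattern families can be registered
as data without touching the parser.

Translation is **total**: a record the grammar cannot read never
raises, it comes back `status="unparsed"` with notes, and curation
routes it to a first-class rejects table so users can report new
patterns. A record translating only to zero (e.g. `0II`) is kept at
the notation layer but flagged `suspicious_zero`; the curated table
itself admits only positive integers, so zero counts are dropped at
curation (with the whole record rejected if nothing positive remains).

`naive_leading_integer` reproduces the lossy baseline of CSV exports
that keep only the first digit run (`40II+44I` → 40); it exists purely
as a comparison column.

## Curation contract

Each parsed record explodes into one row per translated count (a
record translating to "38 38" yields two rows), all rows sharing a
`record_index` and carrying the original string, the full translation,
flags, and the naive parse. Duplicate rows are never collapsed —
frequency means number of records. Genus filtering matches the first
whitespace-delimited token of the binomial, case-insensitively; the
"combined" count-type view keeps gametophytic and sporophytic rows
as-is, with no rescaling, because no single convention is universal;
`double_gametophytic` (CLI `--haploid-double`, default off) rescales
*n* rows to 2*n* for users who want a common scale.

## Summaries and ploidy

Frequencies are exact multiset tallies of (species, count). Heatmap
percentages are normalized **per species** by default (each row sums
to 100), which keeps species with few records comparable; a `global`
mode normalizes by the grand total instead. Modal counts report all
ties ascending rather than breaking them.

Ploidy inference works on the sporophytic scale: a gametophytic count
is doubled, then `p = round(2n / x)` with half-up rounding, clamped to
≥ 1, and the residual `2n − p·x` is reported rather than snapped —
euploidy requires exact divisibility. The base number *x* is always a
user input, as it should come from the cytological literature for the
lineage; `suggest_base_number` offers a gcd-based candidate but is
labeled a heuristic and is never applied automatically.

## Synthetic data

The generator emulates the statistical structure curated count data
display: genera with a shared base number *x* (default drawn uniformly
from 7–40, spanning the range typical of ferns and angiosperms),
species carrying 1–3 even ploidy levels from {2, 4, …, `max_ploidy`
(default 8)}, 1–5 records per species split between gametophytic and
sporophytic types, and an `aneuploid_fraction` (default 0) of records
shifted 1–2 chromosomes off the euploid value (even shifts for
gametophytic records so *n* stays integral). The messifier renders
each true record into one raw string from the documented pattern
families — plain, bivalent/univalent split, B-chromosome addition,
parenthetical metadata, fragment suffix, standalone range,
supernumerary range, `etc` filler — with the bivalent split choosing
`k` uniformly in [⌈c/4⌉, ⌊c/2⌋] so both bivalents and univalents are
usually present. A family that cannot represent a record (the range
family needs two distinct counts) is resampled, with a plain-integer
fallback. Generator and parser share the same family inventory by
construction, and the core tested property is the round trip: curating
a messified table reproduces the ground-truth (taxon, count-type,
count) multiset with zero rejects, for any seed and weight mix.

What the generator does **not** emulate: the empirical frequency of
pattern families in real databases (weights are user parameters),
taxonomic synonymy and name-resolution noise, patterns outside the
documented families, and transcription errors that change the numbers
themselves. Passing round-trip tests therefore demonstrates
correctness of the grammar on its documented families, not coverage of
every pattern a real export can contain — unrecognized real-world
patterns surface in the rejects table by design.

## Numerical and design choices

- All randomness flows through seeded `random.Random` instances; the
  same seed always yields the same table, records, and plots.
- Heatmap row sums are checked to 1e-6 absolute at render time; the
  per-species normalization itself is exact up to float division.
- Stacked-bar colors come from a fixed qualitative palette cycled in
  species sort order, and SVG output pins matplotlib's hash salt and
  strips the embedded date so identical inputs give byte-identical
  files.
- The randomized test and acceptance workloads use a few thousand
  synthetic records and 10⁴ random expressions, sizes chosen to
  exercise every pattern family many times while keeping the suite
  fast on a single CPU.

## Known limitations

- Only the documented pattern families are recognized; the registry is
  the extension point for new ones.
- No taxonomic name resolution: binomials are compared as strings.
- No cross-validation of gametophytic vs sporophytic records of the
  same specimen (n vs 2n consistency), and no model-based inference of
  chromosome-number evolution — the toolkit prepares data for such
  models but does not fit them.
- One published genus-level example lists a tetraploid value (156)
  inconsistent with its own diploid (76, implying 4x = 152); the
  arithmetic here follows the series implied by the diploid and makes
  no attempt to reproduce the inconsistent figure.
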