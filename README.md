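# karyocurate

Curation, summarization, and visualization of plant chromosome-count
records.

## The problem

Public repositories of plant chromosome counts store each observation
as the free-text string a cytologist originally published. Counts made
from meiotic preparations use configuration notation: `40II+44I` means
40 bivalents (each a pair of homologous chromosomes) plus 44
univalents, so the actual complement is 40 + 40 + 44 = 124
chromosomes. Records also carry B chromosomes (`62+1B` — supernumerary,
dispensable chromosomes excluded from the complement), supernumerary
ranges (`34+0-13`), comma- and semicolon-separated alternative
observations, approximate markers (`c.24`), fragment suffixes (`30f`),
parenthetical record-multiplicity metadata (`64(1, 1, 1, 4, 1, 1)`),
and count ranges with assorted unicode dashes (`40‐44`). Naive CSV
exports reduce `40II+44I` to its leading integer, 40, silently losing
most of the complement — a serious problem for anyone building
polyploidy or chromosome-number-evolution datasets.

`karyocurate` parses this notation into clean integer counts with full
provenance, tabulates intra- and interspecific count variation, infers
ploidy levels against a base chromosome number *x* (ploidy *p*
satisfies 2*n* ≈ *p*·*x*), and emits stacked-bar and heatmap plot
data. A seeded synthetic-record generator produces ground-truth tables
and corrupts them into realistic notation, so the entire pipeline is
testable offline by round-trip.

It is aimed at plant evolutionary biologists preparing chromosome-count
data for downstream analyses (e.g. models of polyploidy and dysploidy)
and at instructors teaching karyotype evolution.

## Worked example

```python
from karyocurate import translate_record, naive_leading_integer, infer_ploidy

tr = translate_record("40II+44I")
print(tr.counts)                         # [124]
print(naive_leading_integer("40II+44I")) # 40  (the lossy baseline)

pa = infer_ploidy(124, "sporophytic", base_number_x=31)
print(pa.ploidy_p, pa.euploid)           # 4 True
```

The translator recovers the full 124-chromosome complement where the
leading-integer baseline keeps only 40; against a base number of
*x* = 31 that count is an exact tetraploid (4 × 31 = 124, residual 0).

From the shell, the same pipeline end to end on synthetic data:

```bash
karyocurate simulate --out raw.csv --truth-out truth.csv --seed 3
karyocurate curate --in raw.csv --out curated.csv --rejects-out rejects.csv
karyocurate summarize --in curated.csv --out freq.csv
karyocurate plot --in curated.csv --bar-out bars.svg --heatmap-out heat.png
karyocurate ploidy --in curated.csv --x 38 --genus Anemia
```

`curate` logs `read N records … exploded to M rows, rejected 0` to
stderr; every curated row keeps the original string, the full
translation, flags, and the naive parse for side-by-side comparison.

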