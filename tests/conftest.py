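import pytest

from karyocurate.curate import (
    GAMETOPHYTIC,
    SPOROPHYTIC,
    RawRecord,
    curate_records,
)

# the documented translation examples: raw record -> space-joined counts
DOCUMENTED_TRANSLATIONS = [
    ("40‐44", "40 44"),  # unicode hyphen range
    ("34+0‐13,16,27,30f,etc", "34 16 27 30"),
    ("11II+16I;19II", "38 38"),
    ("62+1B, 62+2Bs, 63, 63+1B, 64(1, 1, 1, 4, 1, 1)", "62 62 63 63 64"),
    ("11II+1BI", "22"),
]


@pytest.fixture
def anemia_like_records():
    """A small genus with a polyploid series on x = 38 (2x..8x) plus an
    outgroup species, mirroring the structure of a real database slice."""
    return [
        RawRecord("Anemia adiantifolia", SPOROPHYTIC, "76"),
        RawRecord("Anemia adiantifolia", SPOROPHYTIC, "76"),
        RawRecord("Anemia adiantifolia", SPOROPHYTIC, "152"),
        RawRecord("Anemia schimperiana", SPOROPHYTIC, "38II"),
        RawRecord("Anemia schimperiana", SPOROPHYTIC, "152"),
        RawRecord("Anemia mexicana", GAMETOPHYTIC, "114"),
        RawRecord("Anemia phyllitidis", SPOROPHYTIC, "304"),
        RawRecord("Blechnum occidentale", SPOROPHYTIC, "40II+44I"),
    ]


@pytest.fixture
def anemia_table(anemia_like_records):
    return curate_records(anemia_like_records)
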