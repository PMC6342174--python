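"""Tests for CSV ingestion and table-level curation."""

import pandas as pd
import pytest

from karyocurate.curate import (
    GAMETOPHYTIC,
    SPOROPHYTIC,
    LONG_DIALECT,
    WIDE_DIALECT,
    CuratedRow,
    RawRecord,
    curate_records,
    double_gametophytic,
    filter_table,
    read_curated_csv,
    read_records,
    write_curated_csv,
    write_rejects_csv,
)


class TestReadRecords:
    def test_long_dialect(self, tmp_path):
        p = tmp_path / "long.csv"
        p.write_text(
            "taxon,count_type,record\n"
            "Anemia adiantifolia,sporophytic,76\n"
            "Anemia adiantifolia,2n,152\n"
            "Anemia mexicana,n,114\n"
        )
        records, skipped = read_records(p, LONG_DIALECT)
        assert skipped == 0
        assert [r.count_type for r in records] == [
            SPOROPHYTIC,
            SPOROPHYTIC,
            GAMETOPHYTIC,
        ]

    def test_wide_dialect_melts_to_long(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text(
            "species,gametophytic,sporophytic\n"
            "Anemia adiantifolia,76,152\n"
            "Anemia mexicana,,304\n"
        )
        records, skipped = read_records(p, WIDE_DIALECT)
        assert skipped == 0
        assert len(records) == 3
        assert records[0].count_type == GAMETOPHYTIC
        assert records[0].record == "76"
        assert records[2].taxon == "Anemia mexicana"

    def test_empty_record_cells_skipped_with_tally(self, tmp_path):
        p = tmp_path / "gaps.csv"
        p.write_text(
            "taxon,count_type,record\n"
            "A b,sporophytic,42\n"
            "C d,sporophytic,\n"
        )
        records, skipped = read_records(p)
        assert len(records) == 1
        assert skipped == 1

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("taxon,record\nA b,42\n")
        with pytest.raises(ValueError, match="count_type"):
            read_records(p)


class TestCurateRecords:
    def test_multi_count_record_explodes_into_rows(self):
        table = curate_records(
            [RawRecord("Gentiana terglouensis", SPOROPHYTIC, "11II+16I;19II")]
        )
        assert [r.count for r in table.rows] == [38, 38]
        assert len({r.record_index for r in table.rows}) == 1
        assert table.rows[0].translation == "38 38"

    def test_unparseable_record_becomes_reject(self):
        table = curate_records([RawRecord("X y", SPOROPHYTIC, "???")])
        assert table.rows == []
        assert len(table.rejects) == 1
        rec, reason = table.rejects[0]
        assert rec.record == "???"
        assert reason

    def test_explosion_conservation(self, anemia_like_records):
        from karyocurate.notation import translate_record

        table = curate_records(anemia_like_records)
        expected = sum(
            len(translate_record(r.record).counts)
            for r in anemia_like_records
        )
        assert len(table.rows) == expected
        assert table.n_source_records == len(anemia_like_records)

    def test_clean_integers_pass_through(self):
        recs = [
            RawRecord(f"Sp {i}", SPOROPHYTIC, str(10 + i)) for i in range(5)
        ]
        table = curate_records(recs)
        assert len(table.rows) == 5
        assert not table.rejects

    def test_counts_are_positive_integers(self, anemia_table):
        for row in anemia_table.rows:
            assert isinstance(row.count, int)
            assert row.count >= 1
            assert str(row.count) in row.translation.split()


class TestFilterTable:
    def test_genus_filter(self, anemia_table):
        out = filter_table(anemia_table, genus="Anemia")
        assert out.rows
        assert all(r.taxon.startswith("Anemia") for r in out.rows)
        assert not any(r.taxon.startswith("Blechnum") for r in out.rows)

    def test_count_type_filter_can_empty_a_table(self, anemia_table):
        sporo_only = filter_table(
            anemia_table, genus="Blechnum", count_type=GAMETOPHYTIC
        )
        assert sporo_only.rows == []

    def test_species_list_is_exact(self, anemia_table):
        out = filter_table(anemia_table, species=["Anemia adiantifolia"])
        assert {r.taxon for r in out.rows} == {"Anemia adiantifolia"}

    def test_combined_keeps_both_types_untransformed(self, anemia_table):
        out = filter_table(anemia_table, genus="Anemia", count_type="combined")
        types = {r.count_type for r in out.rows}
        assert types == {GAMETOPHYTIC, SPOROPHYTIC}
        gameto = [r for r in out.rows if r.count_type == GAMETOPHYTIC]
        assert gameto[0].count == 114  # not doubled

    def test_empty_selection_rejected(self, anemia_table):
        with pytest.raises(ValueError):
            filter_table(anemia_table, species=[])
        with pytest.raises(ValueError):
            filter_table(anemia_table)

    def test_haploid_doubling_is_opt_in(self, anemia_table):
        doubled = double_gametophytic(anemia_table)
        row = next(
            r for r in doubled.rows if "haploid_doubled" in r.flags
        )
        assert row.count == 228
        assert row.count_type == SPOROPHYTIC


class TestCuratedCsv:
    def test_round_trip(self, anemia_table, tmp_path):
        p = tmp_path / "curated.csv"
        write_curated_csv(anemia_table, p)
        back = read_curated_csv(p)
        assert [
            (r.taxon, r.count_type, r.count, r.translation, r.original)
            for r in back.rows
        ] == [
            (r.taxon, r.count_type, r.count, r.translation, r.original)
            for r in anemia_table.rows
        ]

    def test_count_column_is_integer_only(self, anemia_table, tmp_path):
        p = tmp_path / "curated.csv"
        write_curated_csv(anemia_table, p)
        df = pd.read_csv(p, dtype=str)
        assert df["count"].str.fullmatch(r"\d+").all()

    def test_original_and_naive_columns_present(self, tmp_path):
        table = curate_records(
            [RawRecord("Heracleum sphondylium", SPOROPHYTIC, "11II+1BI")]
        )
        p = tmp_path / "curated.csv"
        write_curated_csv(table, p)
        df = pd.read_csv(p)
        assert df.loc[0, "count"] == 22
        assert df.loc[0, "original"] == "11II+1BI"
        assert df.loc[0, "naive_parse"] == 11  # the lossy baseline

    def test_empty_table_writes_header_only(self, tmp_path):
        from karyocurate.curate import CuratedTable

        p = tmp_path / "empty.csv"
        write_curated_csv(CuratedTable(), p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("taxon,count_type,count")

    def test_curation_is_idempotent(self, anemia_table):
        # re-curating the written counts yields the same counts
        again = curate_records(
            [
                RawRecord(r.taxon, r.count_type, str(r.count))
                for r in anemia_table.rows
            ]
        )
        assert [r.count for r in again.rows] == [
            r.count for r in anemia_table.rows
        ]

    def test_rejects_csv(self, tmp_path):
        table = curate_records([RawRecord("X y", SPOROPHYTIC, "???")])
        p = tmp_path / "rejects.csv"
        write_rejects_csv(table, p)
        df = pd.read_csv(p)
        assert list(df.columns) == ["taxon", "count_type", "original", "reason"]
        assert len(df) == 1
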