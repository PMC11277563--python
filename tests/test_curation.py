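import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirstage.curation import (
    DysregulationDB,
    EvidenceRecord,
    load_dysregulation,
    normalize_mirna_id,
    query_direction,
    write_dysregulation,
)
from mirstage.enums import Direction, Qualifier, Source
from mirstage.errors import ParseError, ValidationError


class TestNormalizeMirnaId:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("miR124-3p", "hsa-miR-124-3p"),
            ("hsa-miR-34a-5p", "hsa-miR-34a-5p"),
            ("let-7g-5p", "hsa-let-7g-5p"),
            ("miR-16-1-3p", "hsa-miR-16-1-3p"),
            ("MIR-155-5P", "hsa-miR-155-5p"),
            ("hsa miR 423 - 3p", "hsa-miR-423-3p"),
            ("miR-378a", "hsa-miR-378a"),
        ],
    )
    def test_known_spellings(self, raw, expected):
        assert normalize_mirna_id(raw) == expected

    @pytest.mark.parametrize("bad", ["", "   ", "EGFR", "mirna", "miR-", "let-"])
    def test_rejects_non_mirna_tokens(self, bad):
        with pytest.raises(ValidationError):
            normalize_mirna_id(bad)

    def test_error_names_offending_token(self):
        with pytest.raises(ValidationError, match="EGFR"):
            normalize_mirna_id("EGFR")

    @given(
        st.sampled_from(["", "hsa-", "HSA-"]),
        st.sampled_from(["miR", "mir", "MIR", "let", "LET"]),
        st.sampled_from(["-", ""]),
        st.integers(min_value=1, max_value=9999),
        st.sampled_from(["", "a", "b-1"]),
        st.sampled_from(["", "-3p", "-5p"]),
    )
    def test_idempotent(self, prefix, fam, hyphen, num, letter, arm):
        raw = f"{prefix}{fam}{hyphen}{num}{letter}{arm}"
        once = normalize_mirna_id(raw)
        assert normalize_mirna_id(once) == once

    def test_arm_suffix_preserved(self):
        assert normalize_mirna_id("miR-124-3p").endswith("-3p")
        assert normalize_mirna_id("miR-34a-5p").endswith("-5p")


class TestEvidenceRecord:
    def test_requires_normalized_id(self):
        with pytest.raises(ValidationError):
            EvidenceRecord("miR124-3p", Direction.UP, Source.TISSUE, "r")

    def test_enum_fields_enforced(self):
        with pytest.raises(ValidationError):
            EvidenceRecord("hsa-miR-124-3p", "up", Source.TISSUE, "r")
        with pytest.raises(ValidationError):
            EvidenceRecord("hsa-miR-124-3p", Direction.UP, "tissue", "r")


class TestLoadDysregulation:
    def test_literature_fixture_counts(self, literature_db):
        up_only = {
            m for m in literature_db.mirnas()
            if literature_db.directions_for(m) == {Direction.UP}
        }
        down_only = {
            m for m in literature_db.mirnas()
            if literature_db.directions_for(m) == {Direction.DOWN}
        }
        assert len(up_only) == 7
        assert len(down_only) == 10

    def test_duplicate_rows_collapse(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "mirna_id\tdirection\tsource\treference\n"
            "miR-1-3p\tdown\ttissue\tref\n"
            "hsa-miR-1-3p\tdown\ttissue\tref\n"
        )
        db = load_dysregulation(p)
        assert len(db) == 1

    def test_both_directions_indexed(self, directions_db):
        dirs = directions_db.directions_for("hsa-miR-34a-5p")
        assert dirs == {Direction.UP, Direction.DOWN}

    def test_unknown_source_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "mirna_id\tdirection\tsource\treference\n"
            "miR-1-3p\tdown\ttissue\tref\n"
            "miR-2-3p\tdown\tplasma\tref\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            load_dysregulation(p)

    def test_unknown_direction_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("mirna_id\tdirection\tsource\treference\nmiR-1-3p\tsideways\ttissue\tref\n")
        with pytest.raises(ParseError):
            load_dysregulation(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(ParseError):
            load_dysregulation(p)

    def test_header_only_rejected(self, tmp_path):
        p = tmp_path / "hdr.tsv"
        p.write_text("mirna_id\tdirection\tsource\treference\n")
        with pytest.raises(ParseError):
            load_dysregulation(p)

    def test_saliva_exosome_maps_to_saliva_with_flag(self, tmp_path):
        p = tmp_path / "exo.tsv"
        p.write_text(
            "mirna_id\tdirection\tsource\treference\nmiR-1307-5p\tup\tsaliva_exosome\tref\n"
        )
        (rec,) = load_dysregulation(p).records
        assert rec.source is Source.SALIVA
        assert rec.exosome


class TestRoundTrip:
    def test_tsv_round_trip_identical(self, directions_db, literature_db, tmp_path):
        for i, db in enumerate([directions_db, literature_db]):
            p = tmp_path / f"rt{i}.tsv"
            write_dysregulation(db, p)
            assert load_dysregulation(p) == db

    def test_index_rebuilt_from_records_identical(self, directions_db):
        rebuilt = DysregulationDB(directions_db.records)
        assert rebuilt == directions_db
        assert rebuilt.index.keys() == directions_db.index.keys()


class TestQueryDirection:
    def test_conflicted_mirna_mostly_down(self, directions_db):
        v = query_direction(directions_db, "hsa-miR-34a-5p", Direction.DOWN)
        assert v.passes
        assert v.qualifier is Qualifier.MOSTLY

    def test_conflicted_mirna_rarely_up(self, directions_db):
        v = query_direction(directions_db, "hsa-miR-34a-5p", Direction.UP)
        assert v.passes
        assert v.qualifier is Qualifier.RARELY

    def test_absent_mirna(self, directions_db):
        v = query_direction(directions_db, "hsa-miR-9999-5p", Direction.UP)
        assert not v.passes
        assert v.qualifier is Qualifier.NONE

    def test_consistent_when_no_opposition(self, directions_db):
        v = query_direction(directions_db, "hsa-miR-155-5p", Direction.UP)
        assert v.passes
        assert v.qualifier is Qualifier.CONSISTENT
        assert v.supporting_sources == {Source.TISSUE, Source.SALIVA}

    def test_empty_allowed_sources_rejected(self, directions_db):
        with pytest.raises(ValidationError):
            query_direction(directions_db, "hsa-miR-155-5p", Direction.UP, frozenset())

    def test_excluded_sources_reported_not_counted(self, tmp_path):
        p = tmp_path / "blood.tsv"
        p.write_text(
            "mirna_id\tdirection\tsource\treference\nmiR-21-5p\tup\tblood\tref\n"
        )
        db = load_dysregulation(p)
        v = query_direction(db, "hsa-miR-21-5p", Direction.UP)
        assert not v.passes
        assert len(v.excluded_support) == 1

    def test_monotone_in_allowed_sources(self, directions_db, literature_db):
        small = frozenset({Source.TISSUE})
        big = frozenset({Source.TISSUE, Source.SALIVA, Source.BLOOD, Source.CELL_LINE})
        for db in (directions_db, literature_db):
            for mirna in db.mirnas():
                for direction in Direction:
                    if query_direction(db, mirna, direction, small).passes:
                        assert query_direction(db, mirna, direction, big).passes

    def test_single_direction_evidence_exactly_one_passes(self, literature_db):
        for mirna in literature_db.mirnas():
            if len(literature_db.directions_for(mirna)) != 1:
                continue
            allowed = frozenset(Source)
            outcomes = [
                query_direction(literature_db, mirna, d, allowed).passes for d in Direction
            ]
            assert sum(outcomes) == 1
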