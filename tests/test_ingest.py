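import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contigscope.errors import (
    AnnotationError,
    LinkError,
    RoleError,
    TableError,
    SequenceError,
)
from contigscope.ingest import (
    assign_roles,
    attach,
    compute_sequence_stats,
    read_annotations,
    read_metadata_table,
    write_metadata_table,
)

CSV = "id,gc,taxon\nc1,0.51,Bacteria\nc2,0.62,Archaea\n"
TSV = CSV.replace(",", "\t")


class TestReadMetadataTable:
    def test_basic_parse_kinds_and_values(self):
        table = read_metadata_table(io.StringIO(CSV), dialect="comma")
        assert table.column_names == ["id", "gc", "taxon"]
        assert [c.kind for c in table.columns] == ["ordinal", "numeric", "ordinal"]
        assert len(table) == 2
        assert table.df["gc"].tolist() == [0.51, 0.62]
        assert table.df["taxon"].tolist() == ["Bacteria", "Archaea"]

    def test_auto_dialect_equivalence(self):
        comma = read_metadata_table(io.StringIO(CSV), dialect="auto")
        tab = read_metadata_table(io.StringIO(TSV), dialect="auto")
        assert comma == tab

    @pytest.mark.parametrize(
        "text, match",
        [
            ("id,id\nc1,c2\n", "duplicate"),
            ("", "empty"),
            ("id,gc\nc1,0.5,extra\n", "row 2"),
            ("id,,x\nc1,1,2\n", "empty column name"),
        ],
    )
    def test_malformed_tables_rejected(self, text, match):
        with pytest.raises(TableError, match=match):
            read_metadata_table(io.StringIO(text), dialect="comma")

    def test_auto_dialect_tie_is_an_error(self):
        with pytest.raises(TableError, match="auto-detect"):
            read_metadata_table(io.StringIO("id\tgc,taxon\nc1\t1,x\n"))

    @pytest.mark.parametrize(
        "cell, expected_kind",
        [
            ("1.5e-3", "numeric"),
            ("-42", "numeric"),
            (".5", "numeric"),
            ("1,000", "ordinal"),  # thousands separators are not numbers
            ("1_000", "ordinal"),
            ("nan", "ordinal"),
            ("inf", "ordinal"),
        ],
    )
    def test_numeric_detection(self, cell, expected_kind):
        text = f'id,v\nc1,"{cell}"\n'
        table = read_metadata_table(io.StringIO(text), dialect="comma")
        assert table.spec("v").kind == expected_kind

    def test_missing_cells_become_nan(self):
        table = read_metadata_table(io.StringIO("id,v\nc1,\nc2,3\n"))
        vals = table.df["v"].tolist()
        assert math.isnan(vals[0]) and vals[1] == 3.0


class TestAssignRoles:
    COLS = "id,gc,cov,len,taxon\nc1,0.5,10,1000,Bacteria\nc2,0.6,20,2000,Archaea\n"

    def _table(self, extra=""):
        text = self.COLS
        if extra:
            lines = text.splitlines()
            lines[0] += ",n_genes"
            lines[1] += ",5"
            lines[2] += ",7"
            text = "\n".join(lines) + "\n"
        return read_metadata_table(io.StringIO(text))

    def test_all_numeric_mapped_means_no_filters(self):
        ds = assign_roles(
            self._table(), {"id": "id", "gc": "y", "cov": "x", "len": "size"}
        )
        roles = {c.name: c.role for c in ds.table.columns}
        assert roles == {"id": "id", "gc": "y", "cov": "x", "len": "size",
                         "taxon": "info"}
        assert ds.table.spec("id").kind == "identifier"

    def test_unmapped_numeric_column_becomes_filter(self):
        ds = assign_roles(
            self._table(extra="n_genes"),
            {"id": "id", "gc": "y", "cov": "x", "len": "size"},
        )
        assert ds.table.spec("n_genes").role == "filter"

    @pytest.mark.parametrize(
        "roles, match",
        [
            ({"gc": "y"}, "role 'id'"),
            ({"id": "id", "taxon": "x"}, "numeric"),
            ({"id": "id", "gc": "x", "cov": "x"}, "multiple columns"),
            ({"missing": "id"}, "no such column"),
        ],
    )
    def test_bad_role_maps_rejected(self, roles, match):
        with pytest.raises(RoleError, match=match):
            assign_roles(self._table(), roles)

    def test_duplicate_ids_rejected(self):
        table = read_metadata_table(io.StringIO("id,v\nc1,1\nc1,2\n"))
        with pytest.raises(RoleError, match="duplicate"):
            assign_roles(table, {"id": "id"})


class TestSequenceStats:
    @pytest.mark.parametrize(
        "seq, length, gc",
        [
            ("GGCC", 4, 1.0),
            ("ATATN", 5, 0.0),
            ("NNNN", 4, None),  # no unambiguous base: GC undefined
            ("acgt", 4, 0.5),
            ("GCRYSWN", 7, 1.0),  # ambiguity codes out of the denominator
        ],
    )
    def test_length_and_gc(self, seq, length, gc):
        stats = compute_sequence_stats({"c1": seq})["c1"]
        assert stats["length"] == length
        if gc is None:
            assert stats["gc"] is None
        else:
            assert stats["gc"] == pytest.approx(gc)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(SequenceError):
            compute_sequence_stats({"c1": ""})

    @given(st.text(alphabet="ACGTNacgtnRYKM", min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_gc_invariant_under_case_and_reversal(self, seq):
        base = compute_sequence_stats({"s": seq})["s"]
        for variant in (seq.upper(), seq.lower(), seq[::-1]):
            assert compute_sequence_stats({"s": variant})["s"]["gc"] == base["gc"]


GFF = (
    "##gff-version 3\n"
    "# a comment\n"
    "c1\tsrc\tCDS\t10\t300\t.\t+\t0\tID=g1;product=hypothetical protein\n"
    "c1\tsrc\tCDS\t400\t900\t.\t-\t0\tID=g2;pfam=PF00001\n"
)


class TestReadAnnotations:
    def test_features_parsed_with_attributes(self):
        feats = read_annotations(io.StringIO(GFF))
        assert len(feats) == 2
        f = feats[0]
        assert (f.contig_id, f.start, f.end, f.strand, f.ftype) == (
            "c1", 10, 300, "+", "CDS")
        assert f.attributes["product"] == ("hypothetical protein",)
        assert feats[1].strand == "-"

    @pytest.mark.parametrize(
        "line, match",
        [
            ("c1\tsrc\tCDS\t300\t10\t.\t+\t0\tID=g1", "line 1"),
            ("c1\tsrc\tCDS\tx\t300\t.\t+\t0\tID=g1", "non-integer"),
            ("c1\tsrc\tCDS\t10\t300\t.\t+\t0", "9 tab-separated"),
        ],
    )
    def test_malformed_lines_rejected_with_line_number(self, line, match):
        with pytest.raises(AnnotationError, match=match):
            read_annotations(io.StringIO(line + "\n"))


class TestAttach:
    TABLE = "id,gc\nc1,0.5\nc2,0.6\n"

    def _table(self, text=None):
        return assign_roles(
            read_metadata_table(io.StringIO(text or self.TABLE)), {"id": "id"}
        ).table

    def test_full_attachment(self):
        feats = read_annotations(io.StringIO(GFF))
        ds = attach(self._table(), {"c1": "ACGT", "c2": "GGCC"}, feats)
        assert ds.sequences["c2"] == "GGCC"
        assert len(ds.features_of("c1")) == 2

    def test_unknown_sequence_id_is_an_error(self):
        with pytest.raises(LinkError, match="c3"):
            attach(self._table(), {"c1": "ACGT", "c3": "GG"})

    def test_unknown_annotation_contigs_dropped_with_count(self, caplog):
        feats = read_annotations(
            io.StringIO("cX\tsrc\tCDS\t1\t5\t.\t+\t0\tID=g\n")
        )
        with caplog.at_level("WARNING"):
            ds = attach(self._table(), None, feats)
        assert ds.annotations == []
        assert "dropped 1" in caplog.text

    def test_bare_table_is_a_valid_dataset(self):
        ds = attach(self._table())
        assert ds.sequences is None and ds.annotations is None


# --------------------------------------------------------------------------
# round-trip properties
# --------------------------------------------------------------------------

_name = st.text(alphabet=st.characters(whitelist_categories=("Lu", "Ll")),
                min_size=1, max_size=8)
_text_cell = st.one_of(
    st.just(None),
    st.text(
        alphabet='abcXYZ ,;"\'%-', min_size=1, max_size=12
    ).filter(lambda s: s.strip() != "" and any(c.isalpha() for c in s)),
)
_num_cell = st.one_of(
    st.just(None),
    st.floats(allow_nan=False, allow_infinity=False, width=64,
              min_value=-1e12, max_value=1e12),
)


@st.composite
def tables(draw):
    n_rows = draw(st.integers(min_value=0, max_value=6))
    n_cols = draw(st.integers(min_value=2, max_value=4))
    names = draw(
        st.lists(_name, min_size=n_cols, max_size=n_cols, unique=True)
    )
    lines = [",".join(f'"{n}"' for n in names)]
    kinds = [draw(st.booleans()) for _ in range(n_cols)]  # True = numeric
    for _ in range(n_rows):
        cells = []
        for is_num in kinds:
            v = draw(_num_cell if is_num else _text_cell)
            if v is None:
                cells.append("")
            elif is_num:
                cells.append(repr(v))
            else:
                cells.append('"' + v.replace('"', '""') + '"')
        lines.append(",".join(cells))
    return "\n".join(lines) + "\n"


class TestRoundTrip:
    @given(tables())
    @settings(max_examples=60, deadline=None)
    def test_write_then_read_is_identity(self, csv_text):
        table = read_metadata_table(io.StringIO(csv_text), dialect="comma")
        buf = io.StringIO()
        write_metadata_table(table, buf, dialect="comma")
        buf.seek(0)
        again = read_metadata_table(buf, dialect="comma")
        assert again == table

    @given(tables())
    @settings(max_examples=60, deadline=None)
    def test_comma_and_tab_serializations_parse_equal(self, csv_text):
        table = read_metadata_table(io.StringIO(csv_text), dialect="comma")
        for dialect in ("comma", "tab"):
            buf = io.StringIO()
            write_metadata_table(table, buf, dialect=dialect)
            buf.seek(0)
            assert read_metadata_table(buf, dialect=dialect) == table
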