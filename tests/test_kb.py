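"""GAF parsing, knowledge-base assembly, temporal cutoff, benchmarks."""

import io
import statistics

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gotextcat import (
    AnnotationTriple,
    CuratedDocument,
    KnowledgeBase,
    assemble,
    build_benchmark,
    parse_gaf,
    parse_obo,
    read_abstract_store,
    read_qrels,
    temporal_filter,
    write_abstract_store,
    write_qrels,
)

from conftest import TABLE3_GAF_ROW


def gaf_row(go_id="GO:0000001", ref="PMID:1", date="20080101", evidence="IMP"):
    return (
        f"DB\tOBJ1\tSYM\t\t{go_id}\t{ref}\t{evidence}\t\tP\tname\t\t"
        f"protein\ttaxon:1\t{date}\tsrc\t\t\n"
    )


class TestParseGaf:
    def test_published_entry_becomes_triple(self):
        triples, skipped = parse_gaf(TABLE3_GAF_ROW)
        assert skipped == 0
        assert triples == [
            AnnotationTriple("GO:2000032", "17307924", 2010, evidence_code="IMP")
        ]

    def test_non_pmid_reference_dropped(self):
        triples, skipped = parse_gaf(gaf_row(ref="GO_REF:0000002"))
        assert triples == [] and skipped == 0

    def test_duplicate_pair_keeps_earliest_year(self):
        text = gaf_row(date="20100101") + gaf_row(date="20080601")
        triples, _ = parse_gaf(text)
        assert [t.year for t in triples] == [2008]

    def test_unparseable_date_skipped_and_counted(self):
        text = gaf_row(date="January 2008") + gaf_row(go_id="GO:0000002")
        triples, skipped = parse_gaf(text)
        assert skipped == 1
        assert [t.go_id for t in triples] == ["GO:0000002"]

    def test_comment_and_blank_lines_ignored(self):
        text = "!gaf-version: 2.1\n\n" + gaf_row()
        triples, skipped = parse_gaf(text)
        assert len(triples) == 1 and skipped == 0

    def test_go_id_normalized_through_alt_id(self):
        onto = parse_obo(
            "[Term]\nid: GO:0000005\nname: survivor\nalt_id: GO:0000006\n"
        )
        triples, _ = parse_gaf(gaf_row(go_id="GO:0000006"), onto)
        assert triples[0].go_id == "GO:0000005"

    def test_dashed_date_accepted(self):
        triples, _ = parse_gaf(gaf_row(date="2010-08-23"))
        assert triples[0].year == 2010


def make_kb(years, pub_year=2009):
    """One document per triple year, annotated with one GO term each."""
    docs, triples = {}, set()
    for i, year in enumerate(years, start=1):
        pmid = str(100 + i)
        go_id = f"GO:{i:07d}"
        docs[pmid] = CuratedDocument(
            pmid, pub_year, f"title {i}", f"abstract {i}",
            gold_terms=frozenset({go_id}),
        )
        triples.add(AnnotationTriple(go_id, pmid, year))
    return KnowledgeBase(documents=docs, triples=triples)


class TestTemporalFilter:
    def test_keeps_strictly_earlier_years(self):
        kb = make_kb([2008, 2010, 2012])
        out = temporal_filter(kb, 2010)
        assert {t.year for t in out.triples} == {2008}
        assert len(out.documents) == 1
        assert out.cutoff_year == 2010

    def test_cutoff_above_all_years_is_identity(self):
        kb = make_kb([2008, 2010])
        out = temporal_filter(kb, 2013)
        assert out.triples == kb.triples
        assert set(out.documents) == set(kb.documents)

    def test_cutoff_at_or_below_min_year_annihilates(self):
        kb = make_kb([2008, 2010])
        out = temporal_filter(kb, 2008)
        assert not out.triples and not out.documents

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        years=st.lists(st.integers(2000, 2015), min_size=1, max_size=12),
        a=st.integers(2000, 2016),
        b=st.integers(2000, 2016),
    )
    def test_idempotent_and_monotone(self, years, a, b):
        kb = make_kb(years)
        lo, hi = min(a, b), max(a, b)
        once = temporal_filter(kb, lo)
        assert temporal_filter(once, lo).triples == once.triples
        assert once.triples <= temporal_filter(kb, hi).triples

    def test_filtered_documents_keep_join_consistency(self):
        kb = make_kb([2007, 2009, 2011])
        out = temporal_filter(kb, 2010)
        for pmid, doc in out.documents.items():
            assert doc.gold_terms == out.terms_for(pmid)


class TestAssemble:
    def test_gold_terms_equal_triple_go_ids(self):
        docs = {
            "1": CuratedDocument("1", 2009, "t", "a"),
            "2": CuratedDocument("2", 2009, "t", "a"),
        }
        triples = [
            AnnotationTriple("GO:0000001", "1", 2008),
            AnnotationTriple("GO:0000002", "1", 2008),
            AnnotationTriple("GO:0000001", "2", 2009),
        ]
        kb = assemble(docs, triples)
        assert kb.documents["1"].gold_terms == {"GO:0000001", "GO:0000002"}
        assert kb.documents["2"].gold_terms == {"GO:0000001"}
        for pmid, doc in kb.documents.items():
            assert doc.gold_terms == kb.terms_for(pmid)

    def test_triples_without_stored_document_dropped(self):
        docs = {"1": CuratedDocument("1", 2009, "t", "a")}
        triples = [
            AnnotationTriple("GO:0000001", "1", 2008),
            AnnotationTriple("GO:0000001", "999", 2008),
        ]
        kb = assemble(docs, triples)
        assert len(kb.triples) == 1

    def test_triples_per_pmid_statistics(self):
        docs = {"1": CuratedDocument("1", 2009, "t", "a")}
        triples = [AnnotationTriple(f"GO:{i:07d}", "1", 2008) for i in (1, 2, 3)]
        kb = assemble(docs, triples)
        per_pmid = kb.triples_per_pmid()
        assert statistics.mean(per_pmid.values()) == 3.0
        assert statistics.median(per_pmid.values()) == 3


class TestBuildBenchmark:
    def test_exhaustive_sample_returns_all(self):
        kb = make_kb([2008] * 5, pub_year=2012)
        queries = build_benchmark(kb, 2012, 5, seed=0)
        assert {q.query_id for q in queries} == set(kb.documents)

    def test_oversampling_reports_eligible_count(self):
        kb = make_kb([2008] * 5, pub_year=2012)
        with pytest.raises(ValueError, match="only 5 eligible"):
            build_benchmark(kb, 2012, 6, seed=0)

    def test_seed_determinism(self):
        kb = make_kb([2008] * 30, pub_year=2012)
        first = build_benchmark(kb, 2012, 3, seed=11)
        second = build_benchmark(kb, 2012, 3, seed=11)
        assert first == second
        samples = {
            tuple(q.query_id for q in build_benchmark(kb, 2012, 3, seed=s))
            for s in range(8)
        }
        assert len(samples) > 1  # different seeds explore different samples

    def test_empty_abstract_documents_excluded_by_default(self):
        kb = make_kb([2008] * 3, pub_year=2012)
        first = sorted(kb.documents)[0]
        kb.documents[first].abstract = "  "
        with pytest.raises(ValueError, match="only 2 eligible"):
            build_benchmark(kb, 2012, 3, seed=0)
        assert len(build_benchmark(kb, 2012, 3, seed=0, require_abstract=False)) == 3


class TestAbstractStore:
    def test_line_maps_to_document(self):
        docs = read_abstract_store("17307924\t2007\tT\tA")
        doc = docs["17307924"]
        assert (doc.pmid, doc.pub_year, doc.title, doc.abstract) == (
            "17307924", 2007, "T", "A")

    def test_empty_file_gives_empty_map(self):
        assert read_abstract_store("") == {}

    def test_wrong_column_count_names_line(self):
        with pytest.raises(ValueError, match="line 2"):
            read_abstract_store("1\t2000\tT\tA\n2\t2000\tT")

    def test_roundtrip_with_escaped_newlines(self):
        doc = CuratedDocument("12", 2005, "Two\nline title", "body\nmore")
        buffer = io.StringIO()
        write_abstract_store([doc], buffer)
        assert "\\n" in buffer.getvalue()
        back = read_abstract_store(buffer.getvalue())["12"]
        assert back.title == doc.title and back.abstract == doc.abstract

    def test_embedded_tab_rejected_on_write(self):
        doc = CuratedDocument("12", 2005, "bad\ttitle", "a")
        with pytest.raises(ValueError, match="tab"):
            write_abstract_store([doc], io.StringIO())


class TestQrels:
    def test_write_read_roundtrip(self, small_set):
        _onto, _kb, heldout = small_set
        buffer = io.StringIO()
        write_qrels(heldout, buffer)
        gold = read_qrels(buffer.getvalue())
        assert gold == {q.query_id: q.gold_terms for q in heldout}
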