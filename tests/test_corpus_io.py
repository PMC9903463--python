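"""JSON Lines / CoNLL I/O and span <-> IOB2 conversion."""

import json

import pytest

from coloner.corpus_io import (
    AnnotatedDocument, Span, TaggedSentence, iob2_to_spans, read_annotations,
    read_conll, spans_to_iob2, write_annotations, write_conll,
)
from coloner.errors import ParseError, SchemaError, ValidationError
from coloner.preprocess import sentences_of


def _write_jsonl(path, rows):
    path.write_text("\n".join(json.dumps(r) for r in rows) + "\n")


class TestReadAnnotations:
    def test_single_preparation_span(self, tmp_path):
        p = tmp_path / "a.jsonl"
        _write_jsonl(p, [{"text": "Bowel preparation was fair",
                          "spans": [[22, 26, "PREPARATION"]]}])
        docs = read_annotations(p)
        assert len(docs) == 1
        (span,) = docs[0].spans
        assert (span.start, span.end, span.label, span.text) == (22, 26, "PREPARATION", "fair")

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "e.jsonl"
        p.write_text("")
        assert read_annotations(p) == []

    def test_inverted_span_is_validation_error(self, tmp_path):
        p = tmp_path / "b.jsonl"
        _write_jsonl(p, [{"text": "some text", "spans": [[5, 3, "LESION"]]}])
        with pytest.raises(ValidationError, match="start >= end"):
            read_annotations(p)

    def test_malformed_json_reports_line_number(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text('{"text": "ok", "spans": []}\n{broken\n')
        with pytest.raises(ParseError, match="line 2"):
            read_annotations(p)

    def test_unknown_label_is_schema_error(self, tmp_path):
        p = tmp_path / "d.jsonl"
        _write_jsonl(p, [{"text": "abc", "spans": [[0, 2, "WIDGET"]]}])
        with pytest.raises(SchemaError):
            read_annotations(p)

    def test_entity_object_dialect(self, tmp_path):
        p = tmp_path / "f.jsonl"
        _write_jsonl(p, [{"id": 7, "text": "Bowel preparation was fair",
                          "entities": [{"start_offset": 22, "end_offset": 26,
                                        "label": "PREPARATION"}]}])
        docs = read_annotations(p)
        assert docs[0].doc_id == "7"
        assert docs[0].spans[0].text == "fair"

    def test_round_trip_through_writer(self, tmp_path, tiny_corpus):
        docs, _ = tiny_corpus
        p = tmp_path / "rt.jsonl"
        write_annotations(docs, p)
        back = read_annotations(p)
        assert [(d.doc_id, d.text, d.spans) for d in back] == \
               [(d.doc_id, d.text, d.spans) for d in docs]


class TestSpansToIob2:
    def test_location_phrase_gets_b_then_i(self, tag_vocab):
        text = "on the ascending colon"
        doc = AnnotatedDocument("d", text, [Span(7, 22, "LOCATION", "ascending colon")])
        sents = sentences_of(text, "d")
        (tagged,) = spans_to_iob2(doc, sents, tag_vocab)
        assert tagged.tags == ["O", "O", "B-LOCATION", "I-LOCATION"]

    def test_size_span_from_measurement_phrase(self, tag_vocab):
        text = "about 0.5 cm"
        doc = AnnotatedDocument("d", text, [Span(6, 12, "SIZE", "0.5 cm")])
        (tagged,) = spans_to_iob2(doc, sentences_of(text, "d"), tag_vocab)
        assert tagged.tags == ["O", "B-SIZE", "I-SIZE"]

    def test_document_without_spans_is_all_outside(self, tag_vocab):
        text = "the exam was unremarkable"
        doc = AnnotatedDocument("d", text, [])
        (tagged,) = spans_to_iob2(doc, sentences_of(text, "d"), tag_vocab)
        assert tagged.tags == ["O"] * 4

    def test_span_crossing_sentence_boundary_rejected(self, tag_vocab):
        text = "first line\nsecond line"
        doc = AnnotatedDocument("d", text, [Span(6, 17, "LESION", "line\nsecond")])
        with pytest.raises(ValidationError, match="crosses a sentence boundary"):
            spans_to_iob2(doc, sentences_of(text, "d"), tag_vocab)


class TestIob2ToSpans:
    def test_recovers_location_span(self, tag_vocab):
        text = "on the ascending colon"
        sent = TaggedSentence(tokens=["on", "the", "ascending", "colon"],
                              tags=["O", "O", "B-LOCATION", "I-LOCATION"],
                              char_offsets=[(0, 2), (3, 6), (7, 16), (17, 22)])
        (span,) = iob2_to_spans(sent, text=text, vocab=tag_vocab)
        assert (span.start, span.end, span.label, span.text) == (7, 22, "LOCATION", "ascending colon")

    def test_all_outside_yields_no_spans(self, tag_vocab):
        sent = TaggedSentence(tokens=["a", "b"], tags=["O", "O"],
                              char_offsets=[(0, 1), (2, 3)])
        assert iob2_to_spans(sent, vocab=tag_vocab) == []

    def test_adjacent_b_tags_open_two_entities(self, tag_vocab):
        sent = TaggedSentence(tokens=["polyp", "ulcer"],
                              tags=["B-LESION", "B-LESION"],
                              char_offsets=[(0, 5), (6, 11)])
        spans = iob2_to_spans(sent, vocab=tag_vocab)
        assert len(spans) == 2
        assert [s.label for s in spans] == ["LESION", "LESION"]

    def test_orphan_inside_tag_strict_vs_lenient(self, tag_vocab):
        sent = TaggedSentence(tokens=["on", "colon"], tags=["O", "I-LOCATION"],
                              char_offsets=[(0, 2), (3, 8)])
        with pytest.raises(ValidationError):
            iob2_to_spans(sent, vocab=tag_vocab, strict=True)
        (span,) = iob2_to_spans(sent, vocab=tag_vocab, strict=False)
        assert (span.start, span.end, span.label) == (3, 8, "LOCATION")


class TestConll:
    def test_round_trip(self, tmp_path, tag_vocab):
        sents = [
            TaggedSentence(tokens=["on", "the", "ascending", "colon"],
                           tags=["O", "O", "B-LOCATION", "I-LOCATION"],
                           doc_id="doc-1", sentence_index=0),
            TaggedSentence(tokens=["polyp"], tags=["B-LESION"],
                           doc_id="doc-1", sentence_index=1),
        ]
        p = tmp_path / "x.conll"
        write_conll(sents, p)
        back = list(read_conll(p, tag_vocab))
        assert [(s.tokens, s.tags, s.doc_id, s.sentence_index) for s in back] == \
               [(s.tokens, s.tags, s.doc_id, s.sentence_index) for s in sents]
        # bit-exact: writing the read-back stream reproduces the file
        p2 = tmp_path / "y.conll"
        write_conll(back, p2)
        assert p.read_text() == p2.read_text()

    def test_one_sentence_four_lines(self, tmp_path, tag_vocab):
        p = tmp_path / "s.conll"
        p.write_text("a\tO\nb\tO\nc\tB-LESION\nd\tI-LESION\n\n")
        (sent,) = read_conll(p, tag_vocab)
        assert len(sent) == 4

    def test_pad_tag_cannot_be_serialized(self, tmp_path):
        sent = TaggedSentence(tokens=["a", "b"], tags=["O", "PAD"])
        with pytest.raises(ValidationError, match="PAD"):
            write_conll([sent], tmp_path / "p.conll")

    def test_missing_tag_column_reports_line(self, tmp_path, tag_vocab):
        p = tmp_path / "bad.conll"
        p.write_text("a\tO\nbroken-line\n")
        with pytest.raises(ParseError, match="line 2"):
            list(read_conll(p, tag_vocab))


class TestRoundTripProperty:
    def test_generated_documents_round_trip_exactly(self, tiny_corpus, tag_vocab):
        """spans -> IOB2 -> spans is the identity on generator output."""
        docs, _ = tiny_corpus
        for doc in docs:
            tagged = spans_to_iob2(doc, sentences_of(doc.text, doc.doc_id), tag_vocab)
            got = []
            for sent in tagged:
                got.extend(iob2_to_spans(sent, text=doc.text, vocab=tag_vocab))
            assert sorted((s.start, s.end, s.label) for s in got) == \
                   [(s.start, s.end, s.label) for s in doc.spans]
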