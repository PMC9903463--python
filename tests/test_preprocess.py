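"""Sentence splitting, tokenization, vocabulary and encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coloner.errors import ConfigError
from coloner.preprocess import (
    Vocabulary, build_vocabulary, encode_and_pad, sentences_of, split_sentences,
    tokenize,
)
from coloner.corpus_io import TaggedSentence

FINDINGS_PARAGRAPH = (
    "On the terminal ileum, several erosions and shallow ulcer were noticed. "
    "There were several outpouching lesions on the ascending colon. "
    "On the distal descending colon, about 0.5 cm sized Is polyp was noticed. "
    "On the rectum, about 0.3 cm sized Is polyp was noticed."
)


class TestSplitSentences:
    def test_findings_paragraph_splits_into_four_recoverable_sentences(self):
        sents = split_sentences(FINDINGS_PARAGRAPH)
        assert len(sents) == 4
        for text, start, end in sents:
            assert FINDINGS_PARAGRAPH[start:end] == text

    def test_text_without_terminator_is_one_sentence(self):
        assert split_sentences("Bowel preparation was fair") == \
            [("Bowel preparation was fair", 0, 26)]

    def test_empty_text(self):
        assert split_sentences("") == []

    def test_newline_always_a_boundary(self):
        sents = split_sentences("Procedure Note\nSedation: Yes")
        assert [s[0] for s in sents] == ["Procedure Note", "Sedation: Yes"]

    def test_decimal_numbers_do_not_split(self):
        sents = split_sentences("about 0.5 cm sized Is polyp. Next sentence here.")
        assert len(sents) == 2
        assert sents[0][0].startswith("about 0.5 cm")

    def test_abbreviation_does_not_split(self):
        sents = split_sentences("Scope reached the T.I. No lesion was seen.")
        assert len(sents) == 1  # "T.I." protected as an abbreviation


class TestTokenize:
    def test_finding_sentence_token_count_equals_whitespace_words(self):
        sent = "On the distal descending colon, about 0.5 cm sized Is polyp was noticed."
        toks = tokenize(sent)
        assert len(toks) == len(sent.split()) == 13
        surfaces = [t.surface for t in toks]
        assert "colon" in surfaces and "colon," not in surfaces
        assert "noticed" in surfaces and "noticed." not in surfaces

    def test_internal_hyphens_and_periods_survive(self):
        assert [t.key for t in tokenize("D-colon")] == ["d-colon"]
        assert [t.surface for t in tokenize("the T.I. was intact")][1] == "T.I."

    def test_whitespace_only(self):
        assert tokenize("   ") == []

    def test_offsets_index_the_original_text(self):
        sent = "  (paradoxical response: no)  "
        for t in tokenize(sent):
            assert sent[t.start:t.end] == t.surface

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet=st.characters(min_codepoint=32, max_codepoint=126),
                   max_size=80))
    def test_cleaning_never_changes_word_count(self, text):
        """Normalization must not alter the number or position of words."""
        for sent, start, _end in split_sentences(text):
            toks = tokenize(sent, offset=start)
            assert len(toks) == len(sent.split())
            for t in toks:
                assert text[t.start:t.end] == t.surface

    def test_offsets_compose_document_to_sentence_to_token(self, tiny_corpus):
        docs, _ = tiny_corpus
        for doc in docs[:5]:
            for sent in sentences_of(doc.text, doc.doc_id):
                for tok, (s, e) in zip(sent.tokens, sent.char_offsets):
                    assert doc.text[s:e] == tok


class TestVocabulary:
    def test_min_count_threshold(self):
        v = build_vocabulary(["polyp", "polyp", "ulcer"], min_count=2)
        assert set(v.index) == {"<pad>", "<unk>", "polyp"}
        assert (v.pad_id, v.unk_id) == (0, 1)

    def test_min_count_one_keeps_all_types(self):
        corpus = ["a", "b", "b", "c"]
        v = build_vocabulary(corpus, min_count=1)
        assert len(v) == 3 + 2

    def test_deterministic_index_assignment(self):
        corpus = [["polyp", "ulcer"], ["ulcer", "colon", "polyp"]]
        v1 = build_vocabulary(corpus)
        v2 = build_vocabulary(corpus)
        assert v1.index == v2.index

    def test_min_count_below_one_rejected(self):
        with pytest.raises(ConfigError):
            build_vocabulary(["a"], min_count=0)

    def test_save_load_round_trip(self, tmp_path):
        v = build_vocabulary(["polyp", "polyp", "d-colon"])
        v.save(tmp_path / "vocab.txt")
        back = Vocabulary.load(tmp_path / "vocab.txt")
        assert back.index == v.index


class TestEncodeAndPad:
    def _vocab(self):
        return Vocabulary(index={"<pad>": 0, "<unk>": 1, "polyp": 2, "ulcer": 3})

    def test_padding_and_mask(self, tag_vocab):
        sents = [
            TaggedSentence(tokens=["polyp"], tags=["B-LESION"]),
            TaggedSentence(tokens=["polyp", "ulcer", "polyp"], tags=["O", "O", "O"]),
        ]
        batch = encode_and_pad(sents, self._vocab(), tag_vocab)
        assert batch.token_ids[0].tolist() == [2, 0, 0]
        assert batch.lengths.tolist() == [1, 3]
        assert batch.mask[0].tolist() == [1, 0, 0]
        assert batch.tag_ids[0, 1:].tolist() == [0, 0]  # PAD beyond true length

    def test_out_of_vocabulary_word_maps_to_unk(self, tag_vocab):
        sents = [TaggedSentence(tokens=["bleeingd"], tags=["O"])]
        batch = encode_and_pad(sents, self._vocab(), tag_vocab)
        assert batch.token_ids[0, 0] == 1

    def test_decode_restores_tokens_up_to_unk(self, rng, tag_vocab):
        vocab = build_vocabulary([["on", "the", "colon", "polyp", "was"]])
        words = ["on", "the", "colon", "polyp", "was"]
        for _ in range(20):
            toks = [words[i] for i in rng.integers(0, len(words), rng.integers(1, 6))]
            sents = [TaggedSentence(tokens=toks, tags=["O"] * len(toks))]
            batch = encode_and_pad(sents, vocab, tag_vocab)
            decoded = [vocab.decode(i) for i in batch.token_ids[0, :len(toks)]]
            assert decoded == toks

    def test_truncation_warns(self, tag_vocab):
        sents = [TaggedSentence(tokens=["a"] * 10, tags=["O"] * 10)]
        vocab = self._vocab()
        with pytest.warns(UserWarning, match="truncating"):
            batch = encode_and_pad(sents, vocab, tag_vocab, max_len=4)
        assert batch.token_ids.shape[1] == 4
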