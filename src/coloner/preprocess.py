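"""Sentence splitting, tokenization, vocabulary and integer encoding.

Text cleaning operates under one hard constraint: it must never change the
number or position of words or sentences.  Tokens are therefore exactly the
whitespace-delimited words; normalization only strips edge punctuation from
a token (never deleting a token outright, never merging or splitting across
whitespace).  Internal hyphens and periods survive, so report shorthand
like ``D-colon`` or ``T.I.`` stays a single token.

Vocabulary lookups are case-folded (reports mix ``A-colon``/``a-colon``);
original surfaces and character offsets are preserved alongside.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import TaggedSentence
from .errors import ConfigError
from .schema import TagVocabulary

PAD_WORD = "<pad>"
UNK_WORD = "<unk>"

#: Edge punctuation stripped from tokens during normalization.
EDGE_PUNCT = ",.;:!?()[]{}\"'"

#: Abbreviations after which a period never ends a sentence.
ABBREVIATIONS = {"desc.", "t.i.", "a.", "c.", "s.", "dr.", "no.", "fig.", "approx."}

_SENT_CANDIDATE = re.compile(r"[.!?]\s+(?=[A-Z0-9])|\n+")


@dataclass
class Token:
    surface: str      # normalized surface (edge punctuation stripped)
    raw: str          # original whitespace-delimited word
    start: int        # offset of the normalized surface in the document
    end: int

    @property
    def key(self) -> str:
        """Case-folded form used for vocabulary and embedding lookup."""
        return self.surface.lower()


def split_sentences(text: str) -> list[tuple[str, int, int]]:
    """Split a report into sentences, returning ``(sentence, start, end)``.

    A newline is always a boundary.  A sentence terminator (``.!?``)
    followed by whitespace and a capital/digit is a boundary, unless the
    period closes a known abbreviation or a decimal number (``0.5 cm``).
    Offsets index the original text; surrounding whitespace is trimmed.
    """
    sentences: list[tuple[str, int, int]] = []
    if not text:
        return sentences
    start = 0
    for m in _SENT_CANDIDATE.finditer(text):
        boundary = m.end()
        if "\n" not in m.group():
            # word ending at the terminator; skip boundary after abbreviations
            word_start = max(text.rfind(" ", 0, m.start() + 1),
                             text.rfind("\n", 0, m.start() + 1)) + 1
            word = text[word_start : m.start() + 1].lower()
            if word in ABBREVIATIONS:
                continue
            # decimal numbers never split ("0. 5" cannot occur; guard anyway)
            if re.fullmatch(r"\d+\.", word):
                continue
        chunk = text[start:boundary]
        _append_trimmed(sentences, chunk, start)
        start = boundary
    _append_trimmed(sentences, text[start:], start)
    return sentences


def _append_trimmed(out: list, chunk: str, offset: int) -> None:
    stripped = chunk.strip()
    if not stripped:
        return
    lead = len(chunk) - len(chunk.lstrip())
    out.append((stripped, offset + lead, offset + lead + len(stripped)))


def tokenize(sentence: str, offset: int = 0) -> list[Token]:
    """Whitespace-tokenize a sentence and strip edge punctuation per token.

    The token count always equals the whitespace-word count.  A trailing
    period is kept when the token contains another period (``T.I.``); a
    token that would be emptied by stripping is kept verbatim.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", sentence):
        raw = m.group()
        start, end = m.start() + offset, m.end() + offset
        lead = 0
        while lead < len(raw) and raw[lead] in EDGE_PUNCT:
            lead += 1
        trail = len(raw)
        while trail > lead and raw[trail - 1] in EDGE_PUNCT:
            # keep a trailing period if the token has another period inside
            if raw[trail - 1] == "." and "." in raw[lead : trail - 1]:
                break
            trail -= 1
        if lead == trail:  # all punctuation: keep the token whole
            lead, trail = 0, len(raw)
        tokens.append(Token(surface=raw[lead:trail], raw=raw,
                            start=start + lead, end=start + trail))
    return tokens


def sentences_of(text: str, doc_id: str = "") -> list[TaggedSentence]:
    """Split + tokenize a document into untagged sentences (all-O tags)."""
    out = []
    for i, (sent, s, _e) in enumerate(split_sentences(text)):
        toks = tokenize(sent, offset=s)
        if not toks:
            continue
        out.append(TaggedSentence(
            tokens=[t.surface for t in toks],
            tags=["O"] * len(toks),
            char_offsets=[(t.start, t.end) for t in toks],
            doc_id=doc_id,
            sentence_index=i,
        ))
    return out


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

@dataclass
class Vocabulary:
    """word -> index bijection with reserved PAD=0 and UNK=1 entries."""

    index: dict[str, int]
    frequencies: dict[str, int] = field(default_factory=dict)
    lowercase: bool = True

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, word: str) -> bool:
        return self._fold(word) in self.index

    def _fold(self, word: str) -> str:
        return word.lower() if self.lowercase else word

    def encode(self, word: str) -> int:
        return self.index.get(self._fold(word), self.unk_id)

    def decode(self, idx: int) -> str:
        return self.words[idx]

    @property
    def words(self) -> list[str]:
        out = [""] * len(self.index)
        for w, i in self.index.items():
            out[i] = w
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for w in self.words:
                fh.write(f"{w}\t{self.index[w]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        index: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.rstrip("\n"):
                    continue
                w, i = line.rstrip("\n").split("\t")
                index[w] = int(i)
        return cls(index=index)


def build_vocabulary(
    corpus: Iterable[Sequence[str]] | Iterable[str],
    min_count: int = 1,
    lowercase: bool = True,
) -> Vocabulary:
    """Build a vocabulary from a token stream (or stream of token lists).

    Keeps every token with frequency >= ``min_count`` plus PAD/UNK.  Index
    order is deterministic: descending frequency, ties broken
    lexicographically.
    """
    if min_count < 1:
        raise ConfigError(f"min_count must be >= 1, got {min_count}")
    freq: dict[str, int] = {}
    for item in corpus:
        toks = [item] if isinstance(item, str) else item
        for tok in toks:
            key = tok.lower() if lowercase else tok
            freq[key] = freq.get(key, 0) + 1
    kept = sorted((w for w, c in freq.items() if c >= min_count),
                  key=lambda w: (-freq[w], w))
    index = {PAD_WORD: 0, UNK_WORD: 1}
    for w in kept:
        if w in (PAD_WORD, UNK_WORD):
            continue
        index[w] = len(index)
    return Vocabulary(index=index, frequencies=freq, lowercase=lowercase)


# ---------------------------------------------------------------------------
# Integer encoding and padding
# ---------------------------------------------------------------------------

@dataclass
class EncodedBatch:
    """Integer-encoded, padded sentences with aligned tags and mask."""

    token_ids: np.ndarray   # (n_sentences, max_len) int64, PAD=0 beyond length
    tag_ids: np.ndarray     # (n_sentences, max_len) int64, PAD=0 beyond length
    lengths: np.ndarray     # (n_sentences,) true lengths
    mask: np.ndarray        # (n_sentences, max_len) 1 on real tokens
    sentences: list[TaggedSentence] = field(default_factory=list)

    def __len__(self) -> int:
        return self.token_ids.shape[0]


def encode_and_pad(
    sentences: Sequence[TaggedSentence],
    vocab: Vocabulary,
    tag_vocab: TagVocabulary | None = None,
    max_len: int | None = 128,
) -> EncodedBatch:
    """Encode sentences as padded integer matrices.

    Out-of-vocabulary tokens map to UNK.  Sentences are padded to the batch
    maximum, clipped at ``max_len`` (a sentence longer than the cap is
    truncated with a warning, never silently).
    """
    tag_vocab = tag_vocab or TagVocabulary()
    if not sentences:
        return EncodedBatch(
            token_ids=np.zeros((0, 0), dtype=np.int64),
            tag_ids=np.zeros((0, 0), dtype=np.int64),
            lengths=np.zeros(0, dtype=np.int64),
            mask=np.zeros((0, 0), dtype=np.int64),
        )
    batch_max = max(len(s) for s in sentences)
    if max_len is not None and batch_max > max_len:
        import warnings
        warnings.warn(
            f"truncating {sum(len(s) > max_len for s in sentences)} sentence(s) "
            f"to the {max_len}-token cap", stacklevel=2)
        batch_max = max_len
    n = len(sentences)
    token_ids = np.zeros((n, batch_max), dtype=np.int64)
    tag_ids = np.zeros((n, batch_max), dtype=np.int64)
    lengths = np.zeros(n, dtype=np.int64)
    for i, sent in enumerate(sentences):
        L = min(len(sent), batch_max)
        lengths[i] = L
        for j in range(L):
            token_ids[i, j] = vocab.encode(sent.tokens[j])
            tag_ids[i, j] = tag_vocab.index(sent.tags[j])
    mask = (np.arange(batch_max)[None, :] < lengths[:, None]).astype(np.int64)
    return EncodedBatch(token_ids=token_ids, tag_ids=tag_ids, lengths=lengths,
                        mask=mask, sentences=list(sentences))
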